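"""Published repeat sequences of spirotrich mitogenomes.

Telomeric repeat units and central-repeat compositions reported for the
class Spirotrichea (GenBank accessions in parentheses).  These printed
sequences serve as realistic inputs for reconstructing repeat regions and
validating the detectors without downloading the full assemblies.
"""

from __future__ import annotations

# 5'-end telomeric repeat units, 5'->3'; the 3' array of each genome is the
# reverse complement.  Species without a detected telomere are omitted.
TELOMERE_UNITS: dict[str, str] = {
    "Strombidium_sp": "CTCCCTTATCTAGTCTTT",                      # MT471315, 18 bp
    "Strombidium_cf_sulcatum": "TTATATCCTTTCTCCCCTATATCTCTATAGTACT",  # MT471316, 34 bp
    "Halteria_grandinella": "AAAACAGCTCCGTTCCAATACTACTAACTAA",   # MT471317, 31 bp
    "Oxytricha_trifallax": "CGACTCCTCTATCCTCATCCTAGACTCCGCTTACT",  # JN383843, 35 bp
    "Stylonychia_lemnae": "TTCATACCTTTACTAGATACCCGCCTCCGGCTCTCC",  # KX524144, 36 bp (3' end)
    "Laurentiella_strenua": "CCTACTACGCTTCATACGCTAAA",            # KX529838, 23 bp (partial)
    "Urostyla_grandis": "GTAGCACATGTAG",                          # KX494929, 13 bp (3' end)
}

# central tandem repeats: (region_length_bp, primary unit, full copies)
CENTRAL_REPEATS: dict[str, tuple[int, str, int]] = {
    "Strombidium_sp": (170, "ATAATATAATAATAT", 11),
    "Strombidium_cf_sulcatum": (142, "ATAAATTTAATTTTA", 2),
    "Halteria_grandinella": (168, "TATACATATAATATATA", 9),
}


def reconstruct_central_region(species: str) -> str:
    """Rebuild a central repeat region from its printed description.

    The region is the unit concatenated to full copies plus a partial
    prefix tail filling the printed region length (for species whose
    remainder is an irregular sequence this reconstruction covers only
    the regular part).
    """
    length, unit, copies = CENTRAL_REPEATS[species]
    core = unit * copies
    tail = length - len(core)
    if tail < 0 or tail >= len(unit):
        # irregular remainder longer than one unit: return the regular core
        return core
    return core + unit[:tail]
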