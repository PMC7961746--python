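"""Detection of the three repeat kinds of linear ciliate mitogenomes.

Linear ciliate mitogenomes carry up to three distinct repeat classes:

* **telomeric repeats** — tandem arrays of a short unit (13-36 bp in
  Spirotrichea) capping each end; the 5' and 3' units are reverse
  complements of each other;
* **central repeats** — an AT-rich, often palindromic tandem repeat near
  the middle of the molecule, located between trnF and trnY, from which
  transcription runs divergently in both directions;
* **terminal inverted repeats (TIR)** — near-identical sequences in
  opposite orientation at the two ends (~1.8-3.1 kb where present).

The tandem detector is exact-match: an array is a maximal region whose
minimal period is the reported unit, optionally ending in a partial copy
(a proper prefix of the unit).  Exactness keeps every call reconstructible
and lets the detector be verified against exhaustive enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from linearmito.genome_io import GeneFeature, LinearMitogenome, round2, composition

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(sequence: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters for reverse complement: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TandemRepeatCall:
    """A maximal exact tandem array: unit x full_copies + partial prefix tail."""

    start: int  # 1-based closed
    end: int
    unit: str
    full_copies: int
    partial_tail_bp: int
    at_content_pct: float

    @property
    def unit_len(self) -> int:
        return len(self.unit)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def reconstruct(self) -> str:
        return self.unit * self.full_copies + self.unit[: self.partial_tail_bp]


@dataclass(frozen=True)
class TelomereCall:
    unit_5p: str
    unit_3p: str
    copies_5p: int
    copies_3p: int
    symmetric: bool
    span_5p: tuple[int, int] = (0, 0)  # genome coordinates of the arrays
    span_3p: tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class TIRCall:
    length_bp: int
    identity_pct: float
    span_5p: tuple[int, int]
    span_3p: tuple[int, int]


@dataclass
class ArchitectureReport:
    genome_id: str
    central_repeat: Optional[TandemRepeatCall] = None
    between_trnF_trnY: bool = False
    divergence_fraction: Optional[float] = None
    telomeres: Optional[TelomereCall] = None
    tir: Optional[TIRCall] = None
    repeat_kinds_present: list[str] = field(default_factory=list)


def _minimal_period(s: str) -> int:
    """Smallest p such that s[i] == s[i+p] for all valid i (KMP failure)."""
    n = len(s)
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k and s[i] != s[k]:
            k = fail[k - 1]
        if s[i] == s[k]:
            k += 1
        fail[i] = k
    return n - fail[-1] if n else 0


def find_tandem_repeats(
    sequence: str,
    min_unit: int = 2,
    max_unit: int = 40,
    min_copies: int = 2,
) -> list[TandemRepeatCall]:
    """Find all maximal exact tandem arrays in a sequence.

    A call covers a maximal region with period equal to its unit length,
    contains at least ``min_copies`` complete copies, and is reported once
    under its smallest primitive unit (``ATATATAT`` is one call with unit
    ``AT``, four copies — never a second call with unit ``ATAT``).  Any
    remainder after the last full copy is a proper prefix of the unit and
    is reported as ``partial_tail_bp``.  Calls are sorted by start, then
    length descending.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if min_unit > max_unit:
        raise ValueError(f"min_unit {min_unit} > max_unit {max_unit}")
    seq = sequence.upper()
    n = len(seq)
    calls: list[TandemRepeatCall] = []
    seen_spans: set[tuple[int, int]] = set()
    for ell in range(min_unit, min(max_unit, n // min_copies) + 1):
        # match[i] == True iff seq[i] == seq[i + ell]
        i = 0
        while i < n - ell:
            if seq[i] != seq[i + ell]:
                i += 1
                continue
            j = i
            while j < n - ell and seq[j] == seq[j + ell]:
                j += 1
            # region [i, j + ell) has period ell, maximal by construction
            region_len = (j + ell) - i
            if region_len // ell >= min_copies:
                region = seq[i : j + ell]
                if _minimal_period(region) == ell and (i, j + ell) not in seen_spans:
                    seen_spans.add((i, j + ell))
                    calls.append(
                        TandemRepeatCall(
                            start=i + 1,
                            end=j + ell,
                            unit=region[:ell],
                            full_copies=region_len // ell,
                            partial_tail_bp=region_len % ell,
                            at_content_pct=composition(region).at_content_pct,
                        )
                    )
            i = j + 1
    # an array strictly contained in a longer array is subsumed by it
    # (e.g. the AT runs inside an AT-rich 15-mer array)
    calls.sort(key=lambda c: (c.start, -c.length))
    kept: list[TandemRepeatCall] = []
    max_end = 0
    for c in calls:
        if c.end > max_end:
            kept.append(c)
            max_end = c.end
    return kept


def _rotations(unit: str) -> set[str]:
    return {unit[i:] + unit[:i] for i in range(len(unit))}


def is_rotation(a: str, b: str) -> bool:
    return len(a) == len(b) and a in (b + b)


def find_telomeres(
    genome: LinearMitogenome | str,
    window: int = 500,
    min_unit: int = 6,
    max_unit: int = 60,
    anchor_tolerance: int = 5,
) -> Optional[TelomereCall]:
    """Detect telomeric tandem arrays anchored at the molecule termini.

    Runs the tandem detector inside the first and last ``window`` bp; an
    array qualifies only if it begins within ``anchor_tolerance`` bp of
    its terminus.  Among qualifying 5'/3' pairs the call with the longest
    primitive unit whose 3' unit is (up to rotation) the reverse
    complement of the 5' unit is returned with ``symmetric=True``;
    otherwise the longest-unit terminal arrays are reported without
    symmetry.  Returns None when either terminus lacks an anchored array.
    """
    seq = genome.sequence if isinstance(genome, LinearMitogenome) else genome
    if len(seq) <= 2 * window:
        raise ValueError(f"genome length {len(seq)} must exceed 2 x window ({2 * window})")

    head = seq[:window]
    tail = seq[-window:]
    tail_offset = len(seq) - window

    five = [
        c
        for c in find_tandem_repeats(head, min_unit, max_unit)
        if c.start <= 1 + anchor_tolerance
    ]
    three = [
        c
        for c in find_tandem_repeats(tail, min_unit, max_unit)
        if (tail_offset + c.end) >= len(seq) - anchor_tolerance
    ]
    if not five or not three:
        return None

    # 3' unit in 5'->3' phase as it reaches the terminus; symmetry compares
    # revcomp(unit_3p) against rotations of unit_5p.
    best: Optional[tuple[TandemRepeatCall, TandemRepeatCall]] = None
    for c5 in five:
        for c3 in three:
            if c5.unit_len == c3.unit_len and is_rotation(revcomp(c3.unit), c5.unit):
                if best is None or c5.unit_len > best[0].unit_len:
                    best = (c5, c3)
    if best is not None:
        c5, c3 = best
        symmetric = True
    else:
        c5 = max(five, key=lambda c: c.unit_len)
        c3 = max(three, key=lambda c: c.unit_len)
        symmetric = False
    return TelomereCall(
        unit_5p=c5.unit,
        unit_3p=c3.unit,
        copies_5p=c5.full_copies,
        copies_3p=c3.full_copies,
        symmetric=symmetric,
        span_5p=(c5.start, c5.end),
        span_3p=(tail_offset + c3.start, tail_offset + c3.end),
    )


def find_tir(
    genome: LinearMitogenome | str,
    window: int = 4000,
    min_len: int = 100,
    min_identity_pct: float = 90.0,
    k: int = 16,
    xdrop: int = 20,
) -> Optional[TIRCall]:
    """Detect a terminal inverted repeat by seed-and-extend.

    Exact ``k``-mer seeds between the 5' window and the reverse complement
    of the 3' window are extended without gaps in both directions; an
    extension stops after the running score (match +1, mismatch -1) falls
    ``xdrop`` below its maximum.  The longest extension of at least
    ``min_len`` bp and ``min_identity_pct`` identity is returned, with
    spans in genome coordinates (span_3p on the forward strand).
    """
    seq = genome.sequence if isinstance(genome, LinearMitogenome) else genome
    n = len(seq)
    if n <= 2 * window:
        raise ValueError(f"genome length {n} must exceed 2 x window ({2 * window})")

    a = seq[:window]
    b = revcomp(seq[-window:])  # b[i] pairs genome position n - i (1-based)

    seeds: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        seeds.setdefault(a[i : i + k], []).append(i)

    best: Optional[tuple[int, int, int, int]] = None  # (length, matches, a_start, b_start)
    seen_diag: set[tuple[int, int]] = set()
    for j in range(len(b) - k + 1):
        kmer = b[j : j + k]
        for i in seeds.get(kmer, ()):
            diag = i - j
            # skip seeds inside an already-extended region on this diagonal
            key_found = False
            for (d, lo) in seen_diag:
                if d == diag and lo <= i:
                    key_found = True
                    break
            if key_found:
                continue
            # extend right
            score = best_score = 0
            ei, ej = i + k, j + k
            right_i = ei
            while ei < len(a) and ej < len(b):
                score += 1 if a[ei] == b[ej] else -1
                if score > best_score:
                    best_score, right_i = score, ei + 1
                if best_score - score >= xdrop:
                    break
                ei += 1
                ej += 1
            # extend left
            score = best_score = 0
            si, sj = i - 1, j - 1
            left_i = i
            while si >= 0 and sj >= 0:
                score += 1 if a[si] == b[sj] else -1
                if score > best_score:
                    best_score, left_i = score, si
                if best_score - score >= xdrop:
                    break
                si -= 1
                sj -= 1
            length = right_i - left_i
            b_start = j - (i - left_i)
            matches = sum(
                1 for t in range(length) if a[left_i + t] == b[b_start + t]
            )
            if best is None or length > best[0]:
                best = (length, matches, left_i, b_start)
            seen_diag.add((diag, left_i))

    if best is None:
        return None
    length, matches, a_start, b_start = best
    identity = 100.0 * matches / length
    if length < min_len or identity < min_identity_pct:
        return None
    # b index t corresponds to genome position n - (b_start + t) (1-based)
    span_3p = (n - (b_start + length - 1), n - b_start)
    return TIRCall(
        length_bp=length,
        identity_pct=round2(identity),
        span_5p=(a_start + 1, a_start + length),
        span_3p=span_3p,
    )


def _norm_label(label: str) -> str:
    return label.strip().lower()


def locate_central_repeat(
    genome: LinearMitogenome,
    calls: Sequence[TandemRepeatCall] | None = None,
    at_rich_threshold: float = 80.0,
    min_unit: int = 2,
    max_unit: int = 40,
) -> tuple[Optional[TandemRepeatCall], bool]:
    """Pick the central AT-rich tandem repeat and test its trnF/trnY context.

    Preferred evidence: the highest-A+T tandem call lying in an intergenic
    interval whose flanking annotated features are trnF and trnY (either
    orientation) — the conserved location of the central repeat in
    Spirotrichea.  Fallback without such an interval: the AT-rich call
    (>= ``at_rich_threshold``) whose midpoint is nearest the genome
    midpoint (ties broken by length), with the flag set False.
    """
    if calls is None:
        calls = find_tandem_repeats(genome.sequence, min_unit=min_unit, max_unit=max_unit)
    if not calls:
        return None, False

    feats = sorted(genome.features, key=lambda f: (f.start, f.end))
    intervals: list[tuple[int, int]] = []
    for fa, fb in zip(feats, feats[1:]):
        labels = {_norm_label(fa.label), _norm_label(fb.label)}
        if labels == {"trnf", "trny"} and fb.start > fa.end + 1:
            intervals.append((fa.end + 1, fb.start - 1))

    in_interval = [
        c
        for c in calls
        if any(lo <= c.start and c.end <= hi for lo, hi in intervals)
    ]
    if in_interval:
        return max(in_interval, key=lambda c: (c.at_content_pct, c.length)), True

    mid = (len(genome.sequence) + 1) / 2
    at_rich = [c for c in calls if c.at_content_pct >= at_rich_threshold]
    if not at_rich:
        return None, False
    chosen = min(at_rich, key=lambda c: (-c.length, abs((c.start + c.end) / 2 - mid)))
    return chosen, False


def divergence_fraction(
    genome: LinearMitogenome, center: tuple[int, int]
) -> float:
    """Fraction of genes transcribed away from a central interval.

    A feature entirely left of ``center`` counts as divergent when on
    strand -1; entirely right, when on strand +1.  Features overlapping
    the center are excluded.  In the genomes this package models the
    expectation is 1.0: transcription initiates at the central repeat and
    runs outward on both arms.
    """
    lo, hi = center
    considered = 0
    away = 0
    for f in genome.features:
        if f.end < lo:
            considered += 1
            away += f.strand == -1
        elif f.start > hi:
            considered += 1
            away += f.strand == 1
        # overlapping the center: excluded
    if considered == 0:
        raise ValueError("no features outside the central interval")
    return away / considered


def classify_repeats(
    genome: LinearMitogenome,
    telomere_window: int = 500,
    tir_window: int = 4000,
    at_rich_threshold: float = 80.0,
) -> ArchitectureReport:
    """Compose the three repeat detectors into one architecture report."""
    report = ArchitectureReport(genome_id=genome.id)
    n = len(genome.sequence)

    if n > 2 * telomere_window:
        report.telomeres = find_telomeres(genome, window=telomere_window)
    # a telomeric array is trivially its own inverted repeat at the other
    # end; mask the arrays so a TIR call means additional inverted sequence
    lo = report.telomeres.span_5p[1] if report.telomeres else 0
    hi = report.telomeres.span_3p[0] - 1 if report.telomeres else n
    inner = genome.sequence[lo:hi]
    if len(inner) > 2 * tir_window:
        tir = find_tir(inner, window=tir_window)
        if tir is not None:
            tir = TIRCall(
                length_bp=tir.length_bp,
                identity_pct=tir.identity_pct,
                span_5p=(tir.span_5p[0] + lo, tir.span_5p[1] + lo),
                span_3p=(tir.span_3p[0] + lo, tir.span_3p[1] + lo),
            )
        report.tir = tir

    calls = find_tandem_repeats(genome.sequence)
    # telomeric arrays are tandem calls too; exclude terminal calls from
    # central-repeat candidacy
    interior = [c for c in calls if c.start > telomere_window and c.end <= n - telomere_window]
    central, between = locate_central_repeat(
        genome, interior, at_rich_threshold=at_rich_threshold
    )
    report.central_repeat = central
    report.between_trnF_trnY = between

    if central is not None and genome.features:
        try:
            report.divergence_fraction = divergence_fraction(
                genome, (central.start, central.end)
            )
        except ValueError:
            report.divergence_fraction = None

    kinds = []
    if report.telomeres is not None:
        kinds.append("telomeric")
    if report.central_repeat is not None:
        kinds.append("central")
    if report.tir is not None:
        kinds.append("TIR")
    report.repeat_kinds_present = kinds
    return report
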