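"""Orchestration of the analysis stages into table-style reports.

``characterize`` produces one row per genome mirroring the standard
mitogenome survey columns (size, A+T%, gene/intergenic split, overlap
summary) plus the repeat-architecture columns (central repeat length,
A+T%, unit x copies, telomere unit, TIR length).  ``compare`` produces
the gene presence/absence matrix, all pairwise synteny reports and,
when reference proteins are supplied, split-gene calls.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from linearmito import genome_io, repeats, split_genes, synteny
from linearmito.genome_io import LinearMitogenome

CHARACTERIZE_COLUMNS = [
    "genome", "genome_size_bp", "at_content_pct", "gene_region_bp",
    "intergenic_region_bp", "coding_pct", "overlap_cases", "overlap_min_bp",
    "overlap_max_bp", "overlap_avg_bp", "central_len", "central_AT_pct",
    "unit(copies)", "between_trnF_trnY", "divergence_fraction",
    "telomere_unit", "telomere_symmetric", "TIR_len", "repeat_kinds",
]


def characterize_genome(
    genome: LinearMitogenome,
    telomere_window: int = 500,
    tir_window: int = 4000,
    at_rich_threshold: float = 80.0,
) -> dict:
    """One report row for a genome (empty strings mark absent elements)."""
    comp = genome_io.coding_stats(genome)
    row: dict = {
        "genome": genome.id,
        "genome_size_bp": comp.genome_size_bp,
        "at_content_pct": comp.at_content_pct,
        "gene_region_bp": comp.gene_region_bp if genome.features else "",
        "intergenic_region_bp": comp.intergenic_region_bp if genome.features else "",
        "coding_pct": comp.coding_pct if genome.features else "",
    }
    if genome.features:
        ov = genome_io.overlap_stats(genome.features)
        row.update(
            overlap_cases=ov.n_cases,
            overlap_min_bp=ov.min_bp,
            overlap_max_bp=ov.max_bp,
            overlap_avg_bp=round(ov.avg_bp),
        )
    else:
        row.update(overlap_cases="", overlap_min_bp="", overlap_max_bp="", overlap_avg_bp="")

    arch = repeats.classify_repeats(
        genome,
        telomere_window=telomere_window,
        tir_window=tir_window,
        at_rich_threshold=at_rich_threshold,
    )
    c = arch.central_repeat
    row["central_len"] = c.length if c else ""
    row["central_AT_pct"] = c.at_content_pct if c else ""
    row["unit(copies)"] = f"{c.unit} ({c.full_copies})" if c else ""
    row["between_trnF_trnY"] = arch.between_trnF_trnY
    row["divergence_fraction"] = (
        round(arch.divergence_fraction, 4) if arch.divergence_fraction is not None else ""
    )
    t = arch.telomeres
    row["telomere_unit"] = t.unit_5p if t else ""
    row["telomere_symmetric"] = t.symmetric if t else ""
    row["TIR_len"] = arch.tir.length_bp if arch.tir else ""
    row["repeat_kinds"] = ",".join(arch.repeat_kinds_present)
    return row


def characterize(
    genomes: Sequence[LinearMitogenome],
    out_dir: Optional[str | Path] = None,
    strict: bool = False,
    **detector_kwargs,
) -> pd.DataFrame:
    """Characterise each genome; per-genome failures do not stop the run
    unless ``strict``."""
    rows = []
    errors = []
    for g in genomes:
        try:
            rows.append(characterize_genome(g, **detector_kwargs))
        except Exception as exc:  # pragma: no cover - defensive per-file path
            errors.append((g.id, str(exc)))
            if strict:
                raise
    table = pd.DataFrame(rows, columns=CHARACTERIZE_COLUMNS)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "characterize.tsv", sep="\t", index=False)
        (out / "characterize.json").write_text(
            table.to_json(orient="records", indent=2)
        )
        if errors:
            (out / "errors.json").write_text(json.dumps(dict(errors), indent=2))
    return table


def compare(
    genomes: Sequence[LinearMitogenome],
    out_dir: Optional[str | Path] = None,
    split_reference: Optional[split_genes.ProteinRecord] = None,
    split_orfs: Optional[dict[str, list[split_genes.ProteinRecord]]] = None,
    split_cohort: Optional[Sequence[split_genes.CohortEntry]] = None,
) -> dict:
    """Presence matrix + pairwise synteny (+ optional split-gene calls)."""
    if len(genomes) < 2:
        raise ValueError("compare requires at least two annotated genomes")
    matrix = synteny.presence_matrix(genomes)
    orders = {g.id: synteny.gene_order(g) for g in genomes}

    pairwise = []
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            rep = synteny.collinear_blocks(orders[genomes[i].id], orders[genomes[j].id])
            pairwise.append(rep)

    cassettes = {gid: synteny.trna_cassette(order) for gid, order in orders.items()}

    calls = {}
    if split_reference is not None and split_orfs:
        for gid, orfs in split_orfs.items():
            calls[gid] = split_genes.detect_split(
                orfs, split_reference, split_cohort or []
            )

    result = {
        "presence_matrix": matrix,
        "pairwise": pairwise,
        "trna_cassettes": cassettes,
        "split_calls": calls,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        matrix.to_table().to_csv(out / "presence_matrix.tsv", sep="\t")
        rows = [
            {
                "genomeA": r.genome_a,
                "genomeB": r.genome_b,
                "shared": len(r.shared_genes),
                "blocks": len(r.blocks),
                "breakpoints": r.n_breakpoints,
                "inversions": sum(1 for k, _ in r.rearrangements if k == "inversion"),
                "translocations": sum(1 for k, _ in r.rearrangements if k == "translocation"),
                "identical": r.identical,
            }
            for r in pairwise
        ]
        pd.DataFrame(rows).to_csv(out / "synteny.tsv", sep="\t", index=False)
        if calls:
            payload = {
                gid: {
                    "verdict": c.verdict,
                    "criteria": c.criteria,
                    "split_site": c.split_site,
                    "evidence": {
                        k: v for k, v in c.evidence.items() if not isinstance(v, tuple)
                    },
                }
                for gid, c in calls.items()
            }
            (out / "split_calls.json").write_text(json.dumps(payload, indent=2))
    return result
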