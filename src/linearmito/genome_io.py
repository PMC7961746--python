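"""Sequence and annotation I/O plus per-genome composition statistics.

Coordinates follow the GenBank convention throughout the package: 1-based,
closed intervals.  Strands are +1/-1 integers.  Percentages are rounded
half-up to two decimals, the precision at which mitogenome surveys
customarily report A+T content and coding proportion.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")

CATEGORIES = ("protein", "tRNA", "rRNA", "orf_unknown", "pseudogene")


class ParseError(ValueError):
    """Malformed input file (names the offending record)."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature with 1-based closed coordinates.

    ``part_index`` distinguishes the parts of a split gene (two adjacent
    reading frames encoding the N- and C-terminal halves of one ancestral
    protein); parts share a label and carry part_index 1, 2, ...
    """

    label: str
    category: str
    start: int
    end: int
    strand: int
    part_index: int | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r} for feature {self.label!r}; "
                f"allowed: {', '.join(CATEGORIES)}"
            )
        if self.start < 1:
            raise ValueError(f"feature {self.label!r}: start {self.start} < 1")
        if self.start > self.end:
            raise ValueError(
                f"feature {self.label!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in (1, -1):
            raise ValueError(f"feature {self.label!r}: strand must be +1 or -1")
        if self.part_index is not None and self.part_index < 1:
            raise ValueError(f"feature {self.label!r}: part_index must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class LinearMitogenome:
    """A linear mitogenome: sequence, ordered features, provenance."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    source: str = ""
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"genome {self.id!r}: invalid characters {sorted(bad)}"
            )
        if self.topology != "linear":
            raise ValueError("only linear topologies are supported")
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"feature {f.label!r} end {f.end} exceeds genome "
                    f"length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_features(self, features: Iterable[GeneFeature]) -> "LinearMitogenome":
        return replace(self, features=sorted(features, key=lambda f: (f.start, f.end)))


@dataclass(frozen=True)
class CompositionSummary:
    genome_size_bp: int
    at_content_pct: float
    gene_region_bp: int = 0
    intergenic_region_bp: int = 0
    coding_pct: float = 0.0


@dataclass(frozen=True)
class OverlapSummary:
    n_cases: int
    min_bp: int
    max_bp: int
    avg_bp: float


def round2(x: float) -> float:
    """Round half-up to 2 decimals (table-style reporting)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _normalize(seq: str, record_id: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_BASES
    if bad:
        raise ParseError(
            f"record {record_id!r}: invalid characters {sorted(bad)}"
        )
    return s


def read_fasta(path: str | Path) -> list[LinearMitogenome]:
    """Read a FASTA file into LinearMitogenome records (features empty).

    Sequences are uppercased, U is mapped to T, and any character outside
    {A,C,G,T,N} raises :class:`ParseError` naming the record.
    """
    path = Path(path)
    genomes: list[LinearMitogenome] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ParseError(f"record {rec.id!r}: empty sequence")
        genomes.append(
            LinearMitogenome(
                id=rec.id,
                sequence=_normalize(str(rec.seq), rec.id),
                source=str(path),
            )
        )
    if not genomes:
        raise ParseError(f"{path}: no FASTA records found")
    return genomes


def write_fasta(genomes: Sequence[LinearMitogenome], path: str | Path, width: int = 70) -> None:
    """Write genomes as FASTA, wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


_TSV_COLUMNS = ["label", "category", "start", "end", "strand", "part_index"]

_STRAND_MAP = {"+": 1, "-": -1, "1": 1, "-1": -1, "+1": 1}

_GENBANK_CATEGORY = {
    "CDS": "protein",
    "gene": "protein",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
}


def read_feature_table(path: str | Path, dialect: str = "tsv") -> list[GeneFeature]:
    """Read gene annotations from a TSV table or a GenBank flat file.

    The TSV dialect expects the header
    ``label  category  start  end  strand  part_index`` (tab- or
    comma-separated); strand accepts ``+,-,1,-1``.  The GenBank dialect
    reads gene/CDS/tRNA/rRNA features, with ``complement(...)`` locations
    mapped to strand -1.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_tsv_features(path)
    if dialect == "genbank":
        return _read_genbank_features(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'genbank'")


def _read_tsv_features(path: Path) -> list[GeneFeature]:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(fh, delimiter=delim)
        missing = set(_TSV_COLUMNS[:5]) - set(reader.fieldnames or [])
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        feats = []
        for i, row in enumerate(reader, start=2):
            strand_txt = (row["strand"] or "").strip()
            if strand_txt not in _STRAND_MAP:
                raise ParseError(f"{path}:{i}: bad strand {strand_txt!r}")
            part_txt = (row.get("part_index") or "").strip()
            try:
                feats.append(
                    GeneFeature(
                        label=row["label"].strip(),
                        category=row["category"].strip(),
                        start=int(row["start"]),
                        end=int(row["end"]),
                        strand=_STRAND_MAP[strand_txt],
                        part_index=int(part_txt) if part_txt else None,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: {exc}") from exc
    return feats


def _read_genbank_features(path: Path) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        seen: set[tuple] = set()
        for f in rec.features:
            if f.type not in _GENBANK_CATEGORY:
                continue
            quals = f.qualifiers
            label = (
                quals.get("gene", quals.get("locus_tag", quals.get("product", ["?"])))[0]
            )
            start = int(f.location.start) + 1  # Biopython is 0-based half-open
            end = int(f.location.end)
            strand = 1 if (f.location.strand or 1) >= 0 else -1
            category = _GENBANK_CATEGORY[f.type]
            key = (label, start, end, strand)
            if key in seen:  # gene + CDS pairs describe the same interval
                continue
            seen.add(key)
            feats.append(
                GeneFeature(label=label, category=category, start=start, end=end, strand=strand)
            )
    return feats


def write_feature_table(features: Sequence[GeneFeature], path: str | Path) -> None:
    """Write the bespoke annotation TSV (round-trips with read_feature_table)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_TSV_COLUMNS)
        for f in features:
            writer.writerow(
                [
                    f.label,
                    f.category,
                    f.start,
                    f.end,
                    "+" if f.strand == 1 else "-",
                    f.part_index if f.part_index is not None else "",
                ]
            )


def composition(sequence: str) -> CompositionSummary:
    """Genome size and A+T content of a nucleotide sequence.

    N bases count toward length but not toward A+T, so a sequence with Ns
    can never reach 100%.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    at = seq.count("A") + seq.count("T")
    return CompositionSummary(
        genome_size_bp=len(seq),
        at_content_pct=round2(100.0 * at / len(seq)),
    )


def _interval_union_bp(intervals: Iterable[tuple[int, int]]) -> int:
    """Total bp covered by the union of 1-based closed intervals."""
    ivs = sorted(intervals)
    total = 0
    cur_start, cur_end = None, None
    for s, e in ivs:
        if cur_end is None or s > cur_end + 1:
            if cur_end is not None:
                total += cur_end - cur_start + 1
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start + 1
    return total


def coding_stats(genome: LinearMitogenome) -> CompositionSummary:
    """Gene-region / intergenic-region split of a genome.

    The gene region is the length of the union of all feature intervals:
    bases covered by two overlapping genes are counted once.
    """
    base = composition(genome.sequence)
    gene_bp = _interval_union_bp((f.start, f.end) for f in genome.features)
    return CompositionSummary(
        genome_size_bp=base.genome_size_bp,
        at_content_pct=base.at_content_pct,
        gene_region_bp=gene_bp,
        intergenic_region_bp=base.genome_size_bp - gene_bp,
        coding_pct=round2(100.0 * gene_bp / base.genome_size_bp),
    )


def overlap_stats(features: Sequence[GeneFeature]) -> OverlapSummary:
    """Count pairwise gene overlaps and summarise their lengths.

    A case is an unordered pair of distinct features whose intervals
    intersect, regardless of strand or category; pseudogenes are excluded.
    """
    feats = [f for f in features if f.category != "pseudogene"]
    feats.sort(key=lambda f: (f.start, f.end))
    lengths: list[int] = []
    for i, a in enumerate(feats):
        for b in feats[i + 1 :]:
            if b.start > a.end:
                break
            lengths.append(min(a.end, b.end) - b.start + 1)
    if not lengths:
        return OverlapSummary(n_cases=0, min_bp=0, max_bp=0, avg_bp=0.0)
    return OverlapSummary(
        n_cases=len(lengths),
        min_bp=min(lengths),
        max_bp=max(lengths),
        avg_bp=sum(lengths) / len(lengths),
    )


def translate_code4(dna: str) -> str:
    """Translate DNA under NCBI table 4 (mold/protozoan/coelenterate mt code).

    TGA encodes tryptophan; stops render as ``*``; codons containing a
    non-ACGT character render as ``X``.  A trailing partial codon is
    dropped.
    """
    seq = dna.upper().replace("U", "T")
    usable = len(seq) - len(seq) % 3
    out = []
    for i in range(0, usable, 3):
        codon = seq[i : i + 3]
        if set(codon) - {"A", "C", "G", "T"}:
            out.append("X")
        else:
            out.append(str(Seq(codon).translate(table=4)))
    return "".join(out)
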