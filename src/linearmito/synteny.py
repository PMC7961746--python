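"""Gene complement and gene-order comparison between mitogenomes.

Gene orders are signed label sequences (sign = strand) taken from features
sorted by start.  Collinearity is judged by signed adjacencies: the
adjacency (a, b) is conserved if the other genome contains (a, b) or its
mirror (-b, -a).  Breakpoints are adjacencies of one order absent from the
other.  Rearrangement tags are heuristic — a block whose orientation is
uniformly flipped relative to the partner genome is an inversion, and a
block conserved in orientation but displaced from the collinear backbone
is a translocation — matching how organellar gene-order comparisons are
reported qualitatively, not a minimal rearrangement-distance model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from linearmito.genome_io import GeneFeature, LinearMitogenome

DEFAULT_CASSETTE = ("trnQ", "trnL", "trnE", "trnF", "trnY", "trnW")


@dataclass(frozen=True)
class OrderEntry:
    label: str  # normalized (lower-case)
    strand: int
    occurrence_index: int  # 0-based among same-label entries, by position


@dataclass
class GeneOrder:
    genome_id: str
    entries: list[OrderEntry]

    def signed(self) -> list[tuple[str, int, int]]:
        return [(e.label, e.strand, e.occurrence_index) for e in self.entries]


@dataclass
class SyntenyBlock:
    genes: list[str]
    orientation: str  # "preserved" | "inverted"


@dataclass
class SyntenyReport:
    genome_a: str
    genome_b: str
    shared_genes: list[str]
    blocks: list[SyntenyBlock]
    n_breakpoints: int
    rearrangements: list[tuple[str, tuple[str, ...]]]  # (kind, genes)
    identical: bool
    warning: Optional[str] = None


@dataclass
class PresenceMatrix:
    rows: list[str]  # gene labels
    columns: list[str]  # genome ids
    cells: dict[tuple[str, str], str]  # (gene, genome) -> status

    def to_table(self):
        import pandas as pd

        data = {
            gid: [self.cells.get((g, gid), "absent") for g in self.rows]
            for gid in self.columns
        }
        return pd.DataFrame(data, index=self.rows)


def _norm(label: str) -> str:
    return label.strip().lower()


def gene_order(genome: LinearMitogenome, fuse_split_parts: bool = True) -> GeneOrder:
    """Extract the signed gene order of an annotated genome.

    Split-gene parts (same label, part_index set) that are adjacent in the
    order are fused into one entry; non-adjacent parts remain separate
    entries suffixed ``_i``/``_ii``.  Duplicate labels get occurrence
    indices by position.
    """
    feats = sorted(genome.features, key=lambda f: (f.start, f.end))
    raw: list[tuple[str, int, Optional[int]]] = [
        (_norm(f.label), f.strand, f.part_index) for f in feats
    ]
    fused: list[tuple[str, int]] = []
    i = 0
    while i < len(raw):
        label, strand, part = raw[i]
        if (
            fuse_split_parts
            and part is not None
            and i + 1 < len(raw)
            and raw[i + 1][0] == label
            and raw[i + 1][2] is not None
        ):
            fused.append((label, strand))
            i += 2
            continue
        if part is not None:
            suffix = "_" + "i" * part  # _i, _ii, _iii
            fused.append((label + suffix, strand))
        else:
            fused.append((label, strand))
        i += 1

    counts: dict[str, int] = {}
    entries = []
    for label, strand in fused:
        occ = counts.get(label, 0)
        counts[label] = occ + 1
        entries.append(OrderEntry(label=label, strand=strand, occurrence_index=occ))
    return GeneOrder(genome_id=genome.id, entries=entries)


def presence_matrix(genomes: Sequence[LinearMitogenome]) -> PresenceMatrix:
    """Gene presence/absence/split/duplicated/pseudogene matrix.

    One row per gene label in the union over genomes.  A label with >= 2
    parts (part_index set) is ``split``; >= 2 same-label features without
    part indices is ``duplicated``; pseudogene category wins outright.
    """
    if not genomes:
        raise ValueError("at least one annotated genome required")
    all_labels: list[str] = []
    cells: dict[tuple[str, str], str] = {}
    for g in genomes:
        by_label: dict[str, list[GeneFeature]] = {}
        for f in g.features:
            by_label.setdefault(_norm(f.label), []).append(f)
        for label, feats in by_label.items():
            if label not in all_labels:
                all_labels.append(label)
            if any(f.category == "pseudogene" for f in feats):
                status = "pseudogene"
            elif sum(1 for f in feats if f.part_index is not None) >= 2:
                status = "split"
            elif len(feats) >= 2:
                status = "duplicated"
            else:
                status = "present"
            cells[(label, g.id)] = status
    return PresenceMatrix(
        rows=all_labels, columns=[g.id for g in genomes], cells=cells
    )


def _matched_signed_orders(
    a: GeneOrder, b: GeneOrder
) -> tuple[list[tuple[str, int, int]], list[tuple[str, int, int]], list[str]]:
    """Restrict both orders to shared (label, occurrence) keys.

    Duplicates are matched greedily by positional rank: the k-th copy in A
    pairs with the k-th copy in B; surplus copies are dropped.
    """
    count_a: dict[str, int] = {}
    for e in a.entries:
        count_a[e.label] = count_a.get(e.label, 0) + 1
    count_b: dict[str, int] = {}
    for e in b.entries:
        count_b[e.label] = count_b.get(e.label, 0) + 1
    shared_counts = {
        lab: min(count_a[lab], count_b[lab]) for lab in count_a if lab in count_b
    }
    sa = [
        (e.label, e.strand, e.occurrence_index)
        for e in a.entries
        if e.occurrence_index < shared_counts.get(e.label, 0)
    ]
    sb = [
        (e.label, e.strand, e.occurrence_index)
        for e in b.entries
        if e.occurrence_index < shared_counts.get(e.label, 0)
    ]
    shared = sorted(shared_counts)
    return sa, sb, shared


def _adjacency_key(
    x: tuple[str, int, int], y: tuple[str, int, int]
) -> tuple:
    """Canonical signed adjacency: (x, y) is the same as (-y, -x)."""
    fwd = ((x[0], x[2], x[1]), (y[0], y[2], y[1]))
    rev = ((y[0], y[2], -y[1]), (x[0], x[2], -x[1]))
    return min(fwd, rev)


def collinear_blocks(a: GeneOrder, b: GeneOrder) -> SyntenyReport:
    """Collinear blocks, breakpoints and rearrangement tags for two orders."""
    sa, sb, shared = _matched_signed_orders(a, b)
    if len(shared) < 2:
        return SyntenyReport(
            genome_a=a.genome_id,
            genome_b=b.genome_id,
            shared_genes=shared,
            blocks=[],
            n_breakpoints=0,
            rearrangements=[],
            identical=False,
            warning="fewer than 2 shared genes",
        )

    adj_a = {_adjacency_key(x, y) for x, y in zip(sa, sa[1:])}
    adj_b = {_adjacency_key(x, y) for x, y in zip(sb, sb[1:])}
    n_breakpoints = len(adj_a - adj_b)

    # blocks: maximal runs in A whose successive adjacencies exist in B
    blocks_idx: list[list[int]] = [[0]]
    for i in range(1, len(sa)):
        if _adjacency_key(sa[i - 1], sa[i]) in adj_b:
            blocks_idx[-1].append(i)
        else:
            blocks_idx.append([i])

    pos_b = {(lab, occ): (idx, strand) for idx, (lab, strand, occ) in enumerate(sb)}
    blocks: list[SyntenyBlock] = []
    block_b_pos: list[float] = []
    for idxs in blocks_idx:
        genes = [sa[i][0] for i in idxs]
        b_info = [pos_b[(sa[i][0], sa[i][2])] for i in idxs]
        same = all(strand == sa[i][1] for (_, strand), i in zip(b_info, idxs))
        flipped = all(strand == -sa[i][1] for (_, strand), i in zip(b_info, idxs))
        orientation = "inverted" if (flipped and not same) else "preserved"
        blocks.append(SyntenyBlock(genes=genes, orientation=orientation))
        block_b_pos.append(sum(p for p, _ in b_info) / len(b_info))

    # backbone: longest increasing run of block B-positions (order-conserved
    # blocks); displaced preserved-orientation blocks are translocations
    order_of = sorted(range(len(blocks)), key=lambda i: block_b_pos[i])
    rank = {blk: r for r, blk in enumerate(order_of)}
    lis = _longest_increasing_subsequence([rank[i] for i in range(len(blocks))])
    backbone = set(lis)

    rearrangements: list[tuple[str, tuple[str, ...]]] = []
    for i, blk in enumerate(blocks):
        if blk.orientation == "inverted":
            rearrangements.append(("inversion", tuple(blk.genes)))
        elif i not in backbone:
            rearrangements.append(("translocation", tuple(blk.genes)))

    identical = (
        n_breakpoints == 0
        and len(blocks) == 1
        and blocks[0].orientation == "preserved"
    )
    return SyntenyReport(
        genome_a=a.genome_id,
        genome_b=b.genome_id,
        shared_genes=shared,
        blocks=blocks,
        n_breakpoints=n_breakpoints,
        rearrangements=rearrangements,
        identical=identical,
    )


def _longest_increasing_subsequence(xs: list[int]) -> list[int]:
    """Indices of one longest strictly increasing subsequence."""
    if not xs:
        return []
    import bisect

    tails: list[int] = []  # indices into xs
    prev = [-1] * len(xs)
    for i, x in enumerate(xs):
        lo = bisect.bisect_left([xs[t] for t in tails], x)
        if lo == len(tails):
            tails.append(i)
        else:
            tails[lo] = i
        prev[i] = tails[lo - 1] if lo > 0 else -1
    out = []
    i = tails[-1]
    while i != -1:
        out.append(i)
        i = prev[i]
    return out[::-1]


def trna_cassette(
    order: GeneOrder, cassette: Sequence[str] = DEFAULT_CASSETTE
) -> tuple[str, list[str]]:
    """Check the conserved tRNA cassette (trnQ-trnL-trnE-trnF-trnY-trnW).

    The present cassette members must appear consecutively within the
    tRNA-only subsequence of the order (other tRNAs may not interleave)
    and in cassette order; the whole-cassette reversal is also accepted,
    since an assembly may be reported on either strand.  Returns
    ``("complete", [])``, ``("partial", missing)``, or ``("absent",
    missing)``.
    """
    want = [_norm(x) for x in cassette]
    trnas = [e.label for e in order.entries if e.label.startswith("trn")]
    present = [x for x in want if x in trnas]
    missing = [x for x in want if x not in trnas]
    if not present:
        return "absent", missing

    for target in (present, present[::-1]):
        for i in range(len(trnas) - len(target) + 1):
            if trnas[i : i + len(target)] == target:
                return ("complete" if not missing else "partial"), missing
    return "absent", missing
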