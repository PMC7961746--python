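"""Seeded synthetic linear mitogenomes with planted, manifest-recorded
architecture.

The generator emulates the architecture of spirotrich mitogenomes: a
telomeric tandem array at the 5' end whose reverse complement caps the 3'
end, an optional terminal inverted repeat just inside each terminus, two
gene arms transcribed divergently away from an AT-rich palindromic
central tandem repeat flanked by trnF and trnY (with the conserved tRNA
cassette trnQ-trnL-trnE-trnF-trnY-trnW around it), planted gene overlaps,
and split genes emitted as two adjacent reading frames sharing a label.

Every planted element is recorded in a ground-truth manifest, and the
same parameters always regenerate byte-identical output: one pseudorandom
stream is derived per genome from (seed, genome index).

What it does not emulate: codon structure inside genes, sequencing error
profiles, assembly artefacts, or the irregular partial repeats real
central regions sometimes carry.  Gene bodies are background composition,
which is sufficient for coordinate-level and architecture-level ground
truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from linearmito.genome_io import GeneFeature, LinearMitogenome
from linearmito.repeats import revcomp, _minimal_period

PROTEIN_GENES = [
    "nad1", "nad2", "nad3", "nad4", "nad5", "nad6", "nad7", "nad9", "nad10",
    "nad4L", "cob", "cox1", "cox2", "atp9", "rps2", "rps3", "rps4", "rps7",
    "rps8", "rps10", "rps12", "rps13", "rps14", "rps19", "rpl2", "rpl6",
    "rpl14", "rpl16", "ccmf",
]

CASSETTE_LEFT = ["trnQ", "trnL", "trnE", "trnF"]  # left arm, nearest center last
CASSETTE_RIGHT = ["trnY", "trnW"]

TRNA_LEN = 72
RNL_LEN = 2500
RNS_LEN = 1500


@dataclass
class SimParams:
    """Parameters of one synthetic genome.

    ``telomere_unit`` and ``central_unit`` accept a literal sequence or an
    integer length (a random primitive unit is drawn; central units are
    built AT-palindromic, ``w + revcomp(w)`` over {A,T}, so integer
    lengths must be even).  Defaults mirror the architecture of the
    sequenced spirotrich genomes: ~50 kb, A+T bias 0.77, a 31 bp telomere
    unit, an AT-palindromic 16-mer central unit repeated 11 times with a
    5 bp partial tail, seven overlap events, and nad1/nad2/rps3 split.
    """

    seed: int = 0
    genome_len: int = 50_000
    telomere_unit: Union[str, int] = 31
    telomere_copies: int = 4
    central_unit: Union[str, int] = 16
    central_copies: int = 11
    central_partial_tail: int = 5
    n_genes: int = 45
    gene_len_range: tuple[int, int] = (300, 1500)
    overlap_events: int = 7
    split_genes: tuple[tuple[str, float], ...] = (
        ("nad1", 0.5),
        ("nad2", 0.5),
        ("rps3", 0.5),
    )
    tir_len: int = 0
    at_bias: float = 0.77
    mutation_rate: float = 0.0
    protect_repeats: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.at_bias < 1.0):
            raise ValueError("at_bias must be in (0, 1)")
        if not (0.0 <= self.mutation_rate < 0.5):
            raise ValueError("mutation_rate must be in [0, 0.5)")
        if isinstance(self.central_unit, int) and self.central_unit % 2:
            raise ValueError("integer central_unit length must be even (palindrome)")


@dataclass
class _GenePlan:
    label: str
    category: str
    length: int
    part_index: Optional[int] = None
    spacer_before: int = 10  # bp gap to previous feature; negative = overlap


@dataclass
class _LayoutPlan:
    telomere_unit: str
    telomere_copies: int
    central_unit: str
    central_copies: int
    central_tail: int
    tir_len: int
    left: list[_GenePlan]  # 5' arm, strand -1, listed 5'->3'
    right: list[_GenePlan]  # 3' arm, strand +1
    overlap_pairs: list[tuple[str, str, int]] = field(default_factory=list)


@dataclass
class GroundTruthManifest:
    genome_id: str
    params: dict
    genome_len: int
    telomere: dict  # unit, copies, span_5p, span_3p
    central: dict  # unit, copies, partial_tail_bp, span
    tir: Optional[dict]
    features: list[dict]
    overlap_pairs: list[tuple[str, str, int]]
    split_genes: list[str]

    def to_json(self, **kwargs) -> str:
        return json.dumps(dataclasses.asdict(self), **kwargs)


def _random_seq(rng: np.random.Generator, n: int, at_bias: float) -> str:
    p = [at_bias / 2, (1 - at_bias) / 2, (1 - at_bias) / 2, at_bias / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _random_primitive_unit(rng: np.random.Generator, n: int, at_bias: float) -> str:
    while True:
        unit = _random_seq(rng, n, at_bias)
        if _minimal_period(unit) == n:
            return unit


def _random_at_palindromic_unit(rng: np.random.Generator, n: int) -> str:
    while True:
        w = "".join(np.array(["A", "T"])[rng.integers(0, 2, size=n // 2)])
        unit = w + revcomp(w)
        if _minimal_period(unit) == n:
            return unit


def _plan_layout(params: SimParams, rng: np.random.Generator) -> _LayoutPlan:
    tel_unit = (
        params.telomere_unit
        if isinstance(params.telomere_unit, str)
        else _random_primitive_unit(rng, params.telomere_unit, params.at_bias)
    ).upper()
    cen_unit = (
        params.central_unit
        if isinstance(params.central_unit, str)
        else _random_at_palindromic_unit(rng, params.central_unit)
    ).upper()
    if params.central_partial_tail >= len(cen_unit):
        raise ValueError("central_partial_tail must be shorter than the unit")

    names = list(PROTEIN_GENES)
    n_orfs = max(0, params.n_genes - len(names) - 2)  # 2 rRNAs
    names += [f"orf_s{i + 1}" for i in range(n_orfs)]
    names = names[: params.n_genes - 2]

    genes: list[_GenePlan] = [
        _GenePlan("rnl", "rRNA", RNL_LEN),
        _GenePlan("rns", "rRNA", RNS_LEN),
    ]
    lo, hi = params.gene_len_range
    for name in names:
        cat = "orf_unknown" if name.startswith("orf") else "protein"
        genes.append(_GenePlan(name, cat, int(rng.integers(lo, hi + 1))))

    # split genes -> two adjacent parts sharing the label
    split_map = dict(params.split_genes)
    expanded: list[_GenePlan] = []
    for g in genes:
        if g.label in split_map and g.category in ("protein", "orf_unknown"):
            frac = split_map[g.label]
            k = max(30, int(g.length * frac))
            k = min(k, g.length - 30)
            expanded.append(_GenePlan(g.label, g.category, k, part_index=1))
            expanded.append(
                _GenePlan(g.label, g.category, g.length - k, part_index=2, spacer_before=0)
            )
        else:
            expanded.append(g)

    # keep split parts adjacent: permute "units" (a split pair moves together)
    units: list[list[_GenePlan]] = []
    i = 0
    while i < len(expanded):
        if expanded[i].part_index == 1:
            units.append([expanded[i], expanded[i + 1]])
            i += 2
        else:
            units.append([expanded[i]])
            i += 1
    order = rng.permutation(len(units))
    shuffled = [units[k] for k in order]
    half = len(shuffled) // 2
    left_units, right_units = shuffled[:half], shuffled[half:]

    def flatten(us: list[list[_GenePlan]]) -> list[_GenePlan]:
        out: list[_GenePlan] = []
        for u in us:
            out.extend(u)
        return out

    left = flatten(left_units)
    right = flatten(right_units)
    for g in left + right:
        if g.part_index != 2:
            g.spacer_before = int(rng.integers(2, 51))
    left += [_GenePlan(n, "tRNA", TRNA_LEN, spacer_before=int(rng.integers(2, 51)))
             for n in CASSETTE_LEFT]
    right = [_GenePlan(n, "tRNA", TRNA_LEN, spacer_before=int(rng.integers(2, 51)))
             for n in CASSETTE_RIGHT] + right

    # plant overlaps on junctions between consecutive non-split, non-tRNA genes
    eligible: list[tuple[list[_GenePlan], int]] = []
    for arm in (left, right):
        for idx in range(1, len(arm)):
            a, b = arm[idx - 1], arm[idx]
            if b.part_index == 2 or a.category == "tRNA" or b.category == "tRNA":
                continue
            eligible.append((arm, idx))
    if params.overlap_events > len(eligible):
        raise ValueError(
            f"overlap_events {params.overlap_events} exceeds available junctions "
            f"({len(eligible)})"
        )
    overlap_pairs: list[tuple[str, str, int]] = []
    chosen = rng.choice(len(eligible), size=params.overlap_events, replace=False)
    for c in sorted(int(x) for x in chosen):
        arm, idx = eligible[c]
        a, b = arm[idx - 1], arm[idx]
        ov = int(rng.integers(4, 101))
        ov = min(ov, a.length - 1, b.length - 1)
        b.spacer_before = -ov
        overlap_pairs.append((a.label, b.label, ov))

    return _LayoutPlan(
        telomere_unit=tel_unit,
        telomere_copies=params.telomere_copies,
        central_unit=cen_unit,
        central_copies=params.central_copies,
        central_tail=params.central_partial_tail,
        tir_len=params.tir_len,
        left=left,
        right=right,
        overlap_pairs=overlap_pairs,
    )


def _emit(
    plan: _LayoutPlan,
    params: SimParams,
    rng: np.random.Generator,
    genome_id: str,
) -> tuple[LinearMitogenome, GroundTruthManifest]:
    tel5 = plan.telomere_unit * plan.telomere_copies
    tel3 = revcomp(tel5)
    central = plan.central_unit * plan.central_copies + plan.central_unit[: plan.central_tail]
    tir5 = _random_seq(rng, plan.tir_len, params.at_bias) if plan.tir_len else ""
    tir3 = revcomp(tir5)

    def arm_len(arm: list[_GenePlan]) -> int:
        return sum(g.length + g.spacer_before for g in arm)

    fixed = (
        2 * len(tel5)
        + 2 * len(tir5)
        + len(central)
        + arm_len(plan.left)
        + arm_len(plan.right)
    )
    if fixed > params.genome_len:
        raise ValueError(
            f"planted components need {fixed} bp but genome_len is "
            f"{params.genome_len}; increase genome_len or shrink the layout"
        )
    padding = params.genome_len - fixed
    pad5, pad3 = padding // 2, padding - padding // 2

    chunks: list[str] = []
    features: list[GeneFeature] = []
    pos = 0  # 0-based length so far

    def add(seq: str) -> tuple[int, int]:
        nonlocal pos
        chunks.append(seq)
        span = (pos + 1, pos + len(seq))
        pos += len(seq)
        return span

    span_t5 = add(tel5)
    if tir5:
        add(_random_seq(rng, 20, params.at_bias))  # spacer so TIR != terminus
        span_tir5 = add(tir5)
    else:
        span_tir5 = None
    add(_random_seq(rng, pad5, params.at_bias))

    def emit_arm(arm: list[_GenePlan], strand: int) -> None:
        nonlocal pos
        for g in arm:
            if g.spacer_before > 0:
                add(_random_seq(rng, g.spacer_before, params.at_bias))
                start = pos + 1
                add(_random_seq(rng, g.length, params.at_bias))
            elif g.spacer_before == 0:
                start = pos + 1
                add(_random_seq(rng, g.length, params.at_bias))
            else:  # overlap: feature starts inside the previous one
                ov = -g.spacer_before
                start = pos - ov + 1
                add(_random_seq(rng, g.length - ov, params.at_bias))
            features.append(
                GeneFeature(
                    label=g.label,
                    category=g.category,
                    start=start,
                    end=pos,
                    strand=-strand if getattr(g, "inverted", False) else strand,
                    part_index=g.part_index,
                )
            )

    emit_arm(plan.left, -1)
    span_central = add(central)
    emit_arm(plan.right, +1)
    add(_random_seq(rng, pad3, params.at_bias))
    if tir3:
        span_tir3 = add(tir3)
        add(_random_seq(rng, 20, params.at_bias))
    else:
        span_tir3 = None
    span_t3 = add(tel3)

    seq = list("".join(chunks))
    n = len(seq)

    def guard(pos0: int, forbidden: str) -> None:
        """Force seq[pos0] (0-based) to differ from ``forbidden``."""
        if 0 <= pos0 < n and seq[pos0] == forbidden:
            seq[pos0] = "G" if forbidden != "G" else "C"

    ell = len(plan.telomere_unit)
    # break tandem periodicity just outside each planted array
    guard(span_t5[1], seq[span_t5[1] - ell])  # right of 5' telomere
    guard(span_t3[0] - 2, seq[span_t3[0] - 2 + ell])  # left of 3' telomere
    cl = len(plan.central_unit)
    guard(span_central[0] - 2, seq[span_central[0] - 2 + cl])
    guard(span_central[1], seq[span_central[1] - cl])

    if params.mutation_rate > 0:
        protected = np.zeros(n, dtype=bool)
        if params.protect_repeats:
            for span in (span_t5, span_t3, span_central, span_tir5, span_tir3):
                if span is not None:
                    protected[span[0] - 1 : span[1]] = True
        hits = rng.random(n) < params.mutation_rate
        bases = "ACGT"
        for i in np.nonzero(hits & ~protected)[0]:
            seq[i] = bases[(bases.index(seq[i]) + int(rng.integers(1, 4))) % 4]

    genome = LinearMitogenome(
        id=genome_id,
        sequence="".join(seq),
        features=sorted(features, key=lambda f: (f.start, f.end)),
        source="synthetic",
    )
    resolved = dataclasses.asdict(params)
    resolved["telomere_unit"] = plan.telomere_unit
    resolved["central_unit"] = plan.central_unit
    manifest = GroundTruthManifest(
        genome_id=genome_id,
        params=resolved,
        genome_len=n,
        telomere={
            "unit": plan.telomere_unit,
            "copies": plan.telomere_copies,
            "span_5p": list(span_t5),
            "span_3p": list(span_t3),
        },
        central={
            "unit": plan.central_unit,
            "copies": plan.central_copies,
            "partial_tail_bp": plan.central_tail,
            "span": list(span_central),
        },
        tir=(
            {
                "length_bp": plan.tir_len,
                "span_5p": list(span_tir5),
                "span_3p": list(span_tir3),
            }
            if span_tir5
            else None
        ),
        features=[dataclasses.asdict(f) for f in genome.features],
        overlap_pairs=plan.overlap_pairs,
        split_genes=sorted({g.label for g in plan.left + plan.right if g.part_index}),
    )
    return genome, manifest


def generate_mitogenome(
    params: SimParams, genome_index: int = 0, genome_id: Optional[str] = None
) -> tuple[LinearMitogenome, GroundTruthManifest]:
    """Generate one synthetic genome plus its ground-truth manifest.

    Deterministic: the same (params, genome_index) always produces
    byte-identical output.
    """
    rng = np.random.default_rng([params.seed, genome_index])
    plan = _plan_layout(params, rng)
    gid = genome_id or f"synth_{params.seed}_{genome_index}"
    return _emit(plan, params, rng, gid)


Event = tuple  # ("delete", label) | ("duplicate", label) | ("invert", (l1, l2))
#                | ("translocate", (l1, l2, after_label)) | ("telomere_unit", unit)


def _apply_events(plan: _LayoutPlan, events: Sequence[Event], rng: np.random.Generator) -> list[str]:
    applied = []
    for ev in events:
        kind = ev[0]
        if kind == "delete":
            label = ev[1]
            n0 = len(plan.left) + len(plan.right)
            plan.left = [g for g in plan.left if g.label != label]
            plan.right = [g for g in plan.right if g.label != label]
            if len(plan.left) + len(plan.right) == n0:
                raise ValueError(f"delete: no gene labelled {label!r}")
        elif kind == "duplicate":
            label = ev[1]
            for arm in (plan.left, plan.right):
                for i, g in enumerate(arm):
                    if g.label == label and g.part_index is None:
                        dup = dataclasses.replace(g, spacer_before=int(rng.integers(2, 51)))
                        arm.insert(i + 1, dup)
                        break
                else:
                    continue
                break
            else:
                raise ValueError(f"duplicate: no unsplit gene labelled {label!r}")
        elif kind == "invert":
            l1, l2 = ev[1]
            arm, i1, i2 = _find_segment(plan, l1, l2)
            seg = arm[i1 : i2 + 1]
            seg.reverse()
            for g in seg:
                g.inverted = True  # marker consumed by emit-time strand flip
            arm[i1 : i2 + 1] = seg
        elif kind == "translocate":
            l1, l2, after = ev[1]
            arm, i1, i2 = _find_segment(plan, l1, l2)
            seg = arm[i1 : i2 + 1]
            del arm[i1 : i2 + 1]
            dest_arm, dest_i = None, None
            for cand in (plan.left, plan.right):
                for i, g in enumerate(cand):
                    if g.label == after:
                        dest_arm, dest_i = cand, i
                        break
                if dest_arm is not None:
                    break
            if dest_arm is None:
                raise ValueError(f"translocate: no gene labelled {after!r}")
            dest_arm[dest_i + 1 : dest_i + 1] = seg
        elif kind == "telomere_unit":
            unit = ev[1]
            plan.telomere_unit = (
                unit if isinstance(unit, str)
                else _random_primitive_unit(rng, unit, 0.5)
            )
        else:
            raise ValueError(f"unknown divergence event {kind!r}")
        applied.append(kind)
    # overlaps may have been broken by edits; clear dangling negative spacers
    for arm in (plan.left, plan.right):
        if arm and arm[0].spacer_before < 0:
            arm[0].spacer_before = 10
    return applied


def _find_segment(plan: _LayoutPlan, l1: str, l2: str):
    for arm in (plan.left, plan.right):
        labels = [g.label for g in arm]
        if l1 in labels and l2 in labels:
            i1, i2 = labels.index(l1), labels.index(l2)
            if i1 > i2:
                i1, i2 = i2, i1
            return arm, i1, i2
    raise ValueError(f"segment {l1!r}..{l2!r} not found within one arm")


def generate_cohort(
    base_params: SimParams,
    n: int,
    divergence: Optional[dict[int, Sequence[Event]]] = None,
) -> list[tuple[LinearMitogenome, GroundTruthManifest]]:
    """Generate ``n`` genomes sharing one base architecture.

    ``divergence`` maps a genome index to planted edits: gene deletions
    and duplications, inversions or translocations of gene segments, and
    telomere-unit replacement.  Events are recorded in each manifest.
    Each genome draws from its own (seed, index) stream, so members are
    independently reproducible.
    """
    if n < 2:
        raise ValueError("cohort size must be >= 2")
    divergence = divergence or {}
    n_gene_features = base_params.n_genes + len(CASSETTE_LEFT) + len(CASSETTE_RIGHT)
    for idx, events in divergence.items():
        if len(events) > n_gene_features:
            raise ValueError(f"genome {idx}: more events than genes")
    out = []
    for idx in range(n):
        rng = np.random.default_rng([base_params.seed, idx])
        plan_rng = np.random.default_rng([base_params.seed, 0])
        plan = _plan_layout(base_params, plan_rng)
        applied = _apply_events(plan, divergence.get(idx, ()), rng)
        genome, manifest = _emit(plan, base_params, rng, f"synth_{base_params.seed}_{idx}")
        manifest.params["divergence_events"] = [list(map(str, ev)) for ev in divergence.get(idx, ())]
        out.append((genome, manifest))
    return out
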