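"""Stem-loop modelling of AT-rich central repeats by maximum base pairing.

Central repeats of spirotrich mitogenomes are palindromic tandem arrays
that fold into multi-helix "sun-shape" secondary structures.  This module
models that folding with a Nussinov-style dynamic programme that maximises
the number of Watson-Crick pairs (A·T and G·C; the molecules are DNA, so
no G·U wobble) over nested structures with a minimum hairpin loop.  Pair
counts are exact maxima; helix counts are qualitative descriptors of the
resulting shape, not thermodynamic predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


@dataclass
class StructureModel:
    """A nested secondary structure: pairs are 1-based (i, j) with i < j."""

    sequence: str
    pairs: frozenset[tuple[int, int]]
    helices: list[tuple[int, int, int]] = field(default_factory=list)
    # each helix: (start_i, start_j, stack_len) — pairs (i, j), (i+1, j-1), ...

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def dot_bracket(self) -> str:
        chars = ["." for _ in self.sequence]
        for i, j in self.pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def fold_max_pairing(sequence: str, min_loop: int = 3) -> StructureModel:
    """Fold a sequence into the nested structure with the most base pairs.

    Dynamic programme over intervals: position ``j`` is either unpaired or
    paired with some ``k`` at least ``min_loop + 1`` positions before it.
    Traceback is deterministic — on ties, pairing the interval ends is
    preferred over bifurcation, and the smallest pairing partner wins —
    so identical inputs always give identical structures.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < 2:
        raise ValueError("sequence too short to fold (need >= 2 bases)")

    # N[i][j]: max pairs in seq[i..j], 0-based inclusive
    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i][j - 1]  # j unpaired
            for k in range(i, j - min_loop):
                if _can_pair(seq[k], seq[j]):
                    left = N[i][k - 1] if k > i else 0
                    inner = N[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    cand = left + inner + 1
                    if cand > best:
                        best = cand
            N[i][j] = best

    pairs: set[tuple[int, int]] = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        # prefer pairing j when any partner attains the optimum; only then
        # fall back to leaving j unpaired
        paired = False
        for k in range(i, j - min_loop):  # smallest partner wins ties
            if _can_pair(seq[k], seq[j]):
                left = N[i][k - 1] if k > i else 0
                inner = N[k + 1][j - 1] if k + 1 <= j - 1 else 0
                if left + inner + 1 == N[i][j]:
                    pairs.add((k + 1, j + 1))
                    if k > i:
                        stack.append((i, k - 1))
                    if k + 1 <= j - 1:
                        stack.append((k + 1, j - 1))
                    paired = True
                    break
        if not paired:
            stack.append((i, j - 1))

    model = StructureModel(sequence=seq, pairs=frozenset(pairs))
    model.helices = _maximal_helices(model)
    return model


def _maximal_helices(structure: StructureModel) -> list[tuple[int, int, int]]:
    """Maximal runs of stacked pairs (i,j),(i+1,j-1),... of any length."""
    pairset = structure.pairs
    helices = []
    for i, j in sorted(pairset):
        if (i - 1, j + 1) in pairset:
            continue  # not the outermost pair of its stack
        length = 1
        while (i + length, j - length) in pairset:
            length += 1
        helices.append((i, j, length))
    return helices


def count_helices(structure: StructureModel, min_stack: int = 3) -> int:
    """Number of maximal stacked-pair runs of length >= ``min_stack``."""
    helices = structure.helices or _maximal_helices(structure)
    return sum(1 for (_, _, length) in helices if length >= min_stack)
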