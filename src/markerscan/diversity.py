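"""Nucleotide diversity (pi) and its sliding-window profile.

Pi is the average proportion of differing sites between two sequences drawn
from the alignment, averaged over all unordered pairs. Sites where either
sequence carries a gap or an ambiguity code are excluded pair-wise from both
numerator and denominator (pairwise deletion); a ``complete`` deletion mode
restricted to columns valid in every sequence is also available, since
different population-genetics packages differ on this rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

from .seqio import SequenceCollection, SequenceError

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class WindowPoint:
    window_start: int   # 1-based inclusive alignment column
    window_end: int
    midpoint: float
    pi: float
    n_valid_sites: int  # total valid sites summed over pairs


@dataclass
class DiversityProfile:
    """Sliding-window pi values along an alignment."""

    window_size: int
    step: int
    points: list[WindowPoint]
    overall_pi: float


def pairwise_diff(a: str, b: str) -> tuple[int, int]:
    """(differences, valid_sites) between two equal-length gapped sequences.

    A site is valid iff both characters are concrete bases (A/C/G/T);
    differences counts valid sites where they differ.
    """
    if len(a) != len(b):
        raise SequenceError("sequences must have equal length")
    diff = valid = 0
    for x, y in zip(a, b):
        if x in _ACGT and y in _ACGT:
            valid += 1
            if x != y:
                diff += 1
    return diff, valid


def _complete_columns(seqs: list[str]) -> list[int]:
    n = len(seqs[0])
    return [i for i in range(n) if all(s[i] in _ACGT for s in seqs)]


def nucleotide_diversity(alignment: SequenceCollection, *,
                         deletion: str = "pairwise") -> float:
    """Pi of an aligned collection (n >= 2 sequences).

    Mean over all n(n-1)/2 unordered pairs of differences/valid_sites; pairs
    with zero valid sites are excluded from the mean. Returns NaN if every
    pair is excluded.
    """
    if len(alignment) < 2:
        raise SequenceError("nucleotide diversity needs at least 2 sequences")
    seqs = [r.seq for r in alignment]
    if len({len(s) for s in seqs}) > 1:
        raise SequenceError("sequences must be aligned (equal lengths)")
    if deletion == "complete":
        cols = _complete_columns(seqs)
        seqs = ["".join(s[i] for i in cols) for s in seqs]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")

    total = 0.0
    n_pairs = 0
    for a, b in combinations(seqs, 2):
        d, v = pairwise_diff(a, b)
        if v > 0:
            total += d / v
            n_pairs += 1
    return total / n_pairs if n_pairs else math.nan


def sliding_window_pi(
    alignment: SequenceCollection,
    window_size: int = 100,
    step: int = 10,
    *,
    deletion: str = "pairwise",
    midpoint_offset: float | None = None,
) -> DiversityProfile:
    """Per-window pi profile over alignment columns.

    Windows start at columns 1, 1+step, ... while the window fits entirely in
    the alignment; per-window pi is computed on the window's columns only.
    The reported midpoint is ``start + midpoint_offset``; the default offset
    ``window_size/2 - 1`` puts it at the centre column for even windows.
    """
    if len(alignment) < 2:
        raise SequenceError("nucleotide diversity needs at least 2 sequences")
    length = len(alignment.records[0].seq)
    if length < window_size:
        raise SequenceError(
            f"alignment length {length} shorter than window {window_size}"
        )
    if midpoint_offset is None:
        midpoint_offset = window_size / 2 - 1

    points: list[WindowPoint] = []
    start = 1
    while start + window_size - 1 <= length:
        end = start + window_size - 1
        sub = [r.seq[start - 1:end] for r in alignment]
        total = 0.0
        n_pairs = 0
        valid_total = 0
        if deletion == "complete":
            cols = _complete_columns(sub)
            sub = ["".join(s[i] for i in cols) for s in sub]
        for a, b in combinations(sub, 2):
            d, v = pairwise_diff(a, b)
            valid_total += v
            if v > 0:
                total += d / v
                n_pairs += 1
        pi = total / n_pairs if n_pairs else math.nan
        points.append(WindowPoint(
            window_start=start, window_end=end,
            midpoint=start + midpoint_offset,
            pi=pi, n_valid_sites=valid_total,
        ))
        start += step
    return DiversityProfile(
        window_size=window_size, step=step, points=points,
        overall_pi=nucleotide_diversity(alignment, deletion=deletion),
    )


def expected_star_pi(m: float) -> float:
    """Expected pairwise difference per site for two independent descendants
    of one ancestor, each mutated per site with probability ``m`` (mutant base
    uniform over the 3 alternatives): 2m(1-m) + (2/3)m^2."""
    return 2 * m * (1 - m) + (2.0 / 3.0) * m * m
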