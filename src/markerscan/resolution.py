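"""Mock-community resolution: how many members a primer pair can distinguish.

Each community member's marker sequence is amplified in silico; members whose
products are string-identical form one unit. By default identity is judged on
the amplicon *insert* (primer-binding regions trimmed), because reads of
degenerate-primer products carry primer-encoded variation that is not
biological; ``keep_primers=True`` restores full-product comparison.

A lightweight ZOTU workflow is included for simulated amplicon reads:
exact-string dereplication, annotation of unique sequences against per-strain
reference amplicons by global identity, and read pooling per resolved unit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .primers import Amplicon, PrimerPair, in_silico_pcr
from .seqio import SequenceCollection, SequenceError, SequenceRecord

UNASSIGNED = "unassigned"


@dataclass
class MockCommunity:
    """A defined set of strains with one sequence per marker gene."""

    members: dict[str, dict[str, SequenceRecord]]  # strain_id -> marker -> record

    def __post_init__(self) -> None:
        if not self.members:
            raise SequenceError("community has no members")

    @property
    def strain_ids(self) -> list[str]:
        return list(self.members)

    def marker_sequences(self, marker: str) -> dict[str, SequenceRecord]:
        out = {}
        for strain, markers in self.members.items():
            if marker not in markers:
                raise SequenceError(f"strain {strain!r} lacks marker {marker!r}")
            out[strain] = markers[marker]
        return out


@dataclass
class ResolutionResult:
    """Partition of community members into distinguishable amplified units."""

    pair_name: str
    marker: str
    units: list[list[str]]           # groups of strain_ids sharing one amplicon
    unamplified: list[str]           # members with no in-silico product
    amplicons: dict[str, Amplicon] = field(default_factory=dict)
    per_unit_reads: dict[str, int] | None = None

    @property
    def n_units(self) -> int:
        return len(self.units)

    def unit_of(self, strain_id: str) -> list[str] | None:
        for group in self.units:
            if strain_id in group:
                return group
        return None

    def unit_label(self, group: list[str]) -> str:
        return "/".join(group)


def resolve_community(
    community: MockCommunity,
    marker: str,
    pair: PrimerPair,
    *,
    keep_primers: bool = False,
) -> ResolutionResult:
    """Partition community members by identity of their in-silico amplicon.

    Members with >= 1 product contribute their leftmost amplicon; members with
    none go to the ``unamplified`` group. Identity is exact and
    case-insensitive on the insert (or full product with ``keep_primers``).
    """
    seqs = community.marker_sequences(marker)
    keyed: dict[str, list[str]] = {}
    amplicons: dict[str, Amplicon] = {}
    unamplified: list[str] = []
    order: list[str] = []  # first-seen order of unit keys, for determinism
    for strain, rec in seqs.items():
        products = in_silico_pcr(pair, rec)
        if not products:
            unamplified.append(strain)
            continue
        amp = products[0]  # leftmost
        amplicons[strain] = amp
        key = (amp.seq if keep_primers else amp.insert).upper()
        if key not in keyed:
            keyed[key] = []
            order.append(key)
        keyed[key].append(strain)
    return ResolutionResult(
        pair_name=pair.name,
        marker=marker,
        units=[keyed[k] for k in order],
        unamplified=unamplified,
        amplicons=amplicons,
    )


def dereplicate_reads(reads: SequenceCollection) -> list[tuple[str, int]]:
    """Exact-string dereplication of reads (case-normalised).

    Returns (sequence, count) pairs sorted by descending count, then sequence;
    counts sum to the number of input reads.
    """
    counts = Counter(r.seq.upper() for r in reads)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def _global_identity(a: str, b: str) -> float:
    """Ungapped end-trimmed identity: compare over the shorter length."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    matches = sum(1 for x, y in zip(a[:n], b[:n]) if x == y)
    return matches / n


def annotate_zotus(
    zotus: SequenceCollection,
    references: dict[str, str],
    min_identity: float = 0.97,
) -> dict[str, str]:
    """Assign each ZOTU to the reference strain with highest global identity.

    Ties for the best identity, or a best identity below ``min_identity``,
    yield ``"unassigned"``.
    """
    if not references:
        raise SequenceError("no reference sequences for annotation")
    refs = {k: v.upper() for k, v in references.items()}
    mapping: dict[str, str] = {}
    for z in zotus:
        scored = sorted(
            ((_global_identity(z.seq, ref), strain) for strain, ref in refs.items()),
            key=lambda t: (-t[0], t[1]),
        )
        best, strain = scored[0]
        tie = len(scored) > 1 and scored[1][0] == best
        mapping[z.id] = UNASSIGNED if (tie or best < min_identity) else strain
    return mapping


def pool_and_count(
    mapping: dict[str, str],
    zotu_read_counts: dict[str, int],
    result: ResolutionResult | None = None,
) -> dict[str, int]:
    """Sum read counts per assigned strain, then merge strains into units.

    Unit keys are "/"-joined strain groups of ``result`` (or bare strain ids
    when no partition is given); unassigned reads are reported under
    ``"unassigned"``. Total reads are conserved.
    """
    missing = set(mapping) - set(zotu_read_counts)
    if missing:
        raise SequenceError(f"no read count for zotu(s): {sorted(missing)[:3]}")
    per_strain: Counter[str] = Counter()
    for zotu, strain in mapping.items():
        per_strain[strain] += zotu_read_counts[zotu]

    if result is None:
        return dict(per_strain)

    out: dict[str, int] = {}
    for group in result.units:
        label = result.unit_label(group)
        out[label] = sum(per_strain.pop(s, 0) for s in group)
    unassigned = per_strain.pop(UNASSIGNED, 0)
    # strains not in any unit (unamplified) keep their own key
    for strain, n in per_strain.items():
        out[strain] = n
    if unassigned:
        out[UNASSIGNED] = unassigned
    return out
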