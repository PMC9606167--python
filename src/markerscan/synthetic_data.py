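"""Synthetic genus communities with known truth for end-to-end testing.

The generator emulates the statistical structure of a bacterial genus sampled
through two marker genes: a star phylogeny in which species ancestors are
independent mutants of one genus ancestor (high inter-species divergence) and
strains are independent mutants of their species ancestor (low intra-species
divergence). Each marker template carries an embedded forward primer site and
a reverse-complemented reverse primer site, so every generated genome is
amplifiable by construction — unless a species is deliberately generated with
broken (incompatible) sites. Substitutions are drawn uniformly over the three
alternative bases; no indels are generated, so per-marker collections are
equal-length and gap-free and can feed the diversity and SNP modules without
an aligner.

Every emitted sequence is logged in a truth table (species label, planted
mutation positions, primer-site compatibility, expected amplicon span), which
downstream tests treat as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .primers import PrimerPair, expand_degenerate
from .resolution import MockCommunity
from .seqio import SequenceCollection, SequenceError, SequenceRecord, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_STR = "ACGT"


@dataclass(frozen=True)
class MarkerTemplate:
    """Layout of one marker locus on the synthetic genomes.

    ``fwd_pos`` is the 1-based start of the embedded forward-primer site;
    ``rev_pos`` the 1-based start of the reverse-complemented reverse-primer
    site. ``copies`` > 1 emulates a multi-copy rRNA-like locus whose copies
    within one genome differ at rate ``copy_snp_rate``.
    """

    name: str
    length: int
    pair: PrimerPair
    fwd_pos: int
    rev_pos: int
    copies: int = 1
    copy_snp_rate: float = 0.0

    def __post_init__(self) -> None:
        flen, rlen = len(self.pair.forward), len(self.pair.reverse)
        if self.length < flen + rlen + 50:
            raise SequenceError(
                f"marker {self.name!r}: length {self.length} too short for primers + 50"
            )
        if not (1 <= self.fwd_pos and self.fwd_pos + flen <= self.rev_pos
                and self.rev_pos + rlen - 1 <= self.length):
            raise SequenceError(f"marker {self.name!r}: primer sites out of order/bounds")

    @property
    def amplicon_span(self) -> tuple[int, int]:
        """1-based inclusive (start, end) of the expected product."""
        return (self.fwd_pos, self.rev_pos + len(self.pair.reverse) - 1)

    @property
    def protected(self) -> set[int]:
        """0-based positions inside the two primer sites (kept mutation-free)."""
        f0 = self.fwd_pos - 1
        r0 = self.rev_pos - 1
        return set(range(f0, f0 + len(self.pair.forward))) | set(
            range(r0, r0 + len(self.pair.reverse))
        )


@dataclass
class CommunitySpec:
    """Study conditions for one synthetic genus.

    Defaults give a genus of 10 species x 5 strains with inter-species
    divergence 0.15 substitutions/site and intra-species divergence 0.02 —
    the qualitative regime of a protein-coding marker that separates species
    widely while strains within a species stay nearly identical.
    """

    markers: list[MarkerTemplate]
    n_species: int = 10
    strains_per_species: int = 5
    interspecies_divergence: float = 0.15
    intraspecies_rate: float = 0.02
    n_incompatible_species: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.interspecies_divergence, self.intraspecies_rate):
            if not 0.0 <= p <= 1.0:
                raise SequenceError("divergence rates must be in [0, 1]")
        if not self.markers:
            raise SequenceError("at least one marker template required")
        if self.n_incompatible_species > self.n_species:
            raise SequenceError("more incompatible species than species")


@dataclass(frozen=True)
class TruthRecord:
    seq_id: str
    marker: str
    species: str
    strain: str
    mutated_positions: tuple[int, ...]   # 1-based, relative to the marker
    primer_compatible: bool
    amplicon_span: tuple[int, int] | None


@dataclass
class TruthTable:
    records: list[TruthRecord] = field(default_factory=list)

    def by_id(self, seq_id: str) -> TruthRecord:
        for r in self.records:
            if r.seq_id == seq_id:
                return r
        raise KeyError(seq_id)


@dataclass
class SyntheticCommunity:
    """generate_community output: per-marker collections + community + truth."""

    collections: dict[str, SequenceCollection]
    community: MockCommunity
    truth: TruthTable
    spec: CommunitySpec


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASE_STR[i] for i in rng.integers(0, 4, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            protected: set[int]) -> tuple[str, tuple[int, ...]]:
    """Per-site substitution with probability ``rate`` outside ``protected``.

    The mutant base is uniform over the 3 alternatives. Returns the mutated
    sequence and the 1-based positions actually changed.
    """
    if rate == 0.0:
        return seq, ()
    arr = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    changed = []
    for i in hits:
        if int(i) in protected:
            continue
        old = arr[i]
        alts = [b for b in _BASE_STR if b != old]
        arr[i] = alts[int(rng.integers(0, 3))]
        changed.append(int(i) + 1)
    return "".join(arr), tuple(changed)


def _plant_site(seq: str, pos0: int, site: str) -> str:
    return seq[:pos0] + site + seq[pos0 + len(site):]


def _break_site(primer_seq: str, variant: str) -> str:
    """Corrupt a planted site so no expansion can reach min_match.

    Flipping a base at a *non-degenerate* primer position mismatches every
    expansion; enough such flips push the best match below any threshold.
    """
    out = list(variant)
    flipped = 0
    need = len(variant)  # flip every fixed position: unambiguous incompatibility
    from .seqio import IUPAC_CODES
    for i, code in enumerate(primer_seq):
        allowed = IUPAC_CODES[code]
        choices = [b for b in _BASE_STR if b not in allowed]
        if choices:
            out[i] = choices[0]
            flipped += 1
        if flipped >= need:
            break
    return "".join(out)


def generate_community(spec: CommunitySpec) -> SyntheticCommunity:
    """Generate per-marker sequence collections, a mock community and truth.

    Reproducible given ``spec.seed``. Mutations are never planted inside the
    primer sites of compatible genomes; the last ``n_incompatible_species``
    species get deliberately corrupted sites on every marker and are flagged
    incompatible in the truth table.
    """
    rng = np.random.default_rng(spec.seed)
    collections: dict[str, SequenceCollection] = {}
    members: dict[str, dict[str, SequenceRecord]] = {}
    truth = TruthTable()

    # per-marker genus ancestor with planted primer sites (one fixed expansion)
    ancestors: dict[str, str] = {}
    fwd_variants: dict[str, str] = {}
    rev_variants: dict[str, str] = {}
    for mt in spec.markers:
        base = _random_seq(rng, mt.length)
        fv = min(expand_degenerate(mt.pair.forward))
        rv = min(expand_degenerate(mt.pair.reverse))
        base = _plant_site(base, mt.fwd_pos - 1, fv)
        base = _plant_site(base, mt.rev_pos - 1, reverse_complement(rv))
        ancestors[mt.name] = base
        fwd_variants[mt.name] = fv
        rev_variants[mt.name] = rv

    first_incompatible = spec.n_species - spec.n_incompatible_species
    for mt in spec.markers:
        records: list[SequenceRecord] = []
        for si in range(spec.n_species):
            species = f"Species {si + 1:02d}"
            compatible = si < first_incompatible
            protected = mt.protected if compatible else set()
            sp_anc, _ = _mutate(rng, ancestors[mt.name],
                                spec.interspecies_divergence, mt.protected)
            if not compatible:
                broken_f = _break_site(mt.pair.forward.seq, fwd_variants[mt.name])
                broken_r = _break_site(mt.pair.reverse.seq, rev_variants[mt.name])
                sp_anc = _plant_site(sp_anc, mt.fwd_pos - 1, broken_f)
                sp_anc = _plant_site(sp_anc, mt.rev_pos - 1,
                                     reverse_complement(broken_r))
            for ti in range(spec.strains_per_species):
                strain = f"s{si + 1:02d}_{ti + 1:02d}"
                seq, muts = _mutate(rng, sp_anc, spec.intraspecies_rate, protected)
                for copy in range(mt.copies):
                    if copy == 0:
                        cid, cseq, cmuts = f"{strain}|{mt.name}", seq, muts
                    else:
                        cseq, extra = _mutate(rng, seq, mt.copy_snp_rate, protected)
                        cid = f"{strain}|{mt.name}|copy{copy + 1}"
                        cmuts = tuple(sorted(set(muts) | set(extra)))
                    records.append(SequenceRecord(
                        id=cid, seq=cseq,
                        description=species, taxon_label=species,
                    ))
                    truth.records.append(TruthRecord(
                        seq_id=cid, marker=mt.name, species=species,
                        strain=strain, mutated_positions=cmuts,
                        primer_compatible=compatible,
                        amplicon_span=mt.amplicon_span if compatible else None,
                    ))
                members.setdefault(strain, {})[mt.name] = SequenceRecord(
                    id=f"{strain}|{mt.name}", seq=seq,
                    description=species, taxon_label=species,
                )
        collections[mt.name] = SequenceCollection(records=records, aligned=False)

    return SyntheticCommunity(
        collections=collections,
        community=MockCommunity(members=members),
        truth=truth,
        spec=spec,
    )


def simulate_star_alignment(
    n_sequences: int,
    length: int,
    mutation_rate: float,
    rng: np.random.Generator | int | None = None,
) -> SequenceCollection:
    """Star-topology sample: n independent per-site mutants of one ancestor.

    The analytic expected pairwise difference per site between two such
    mutants is 2m(1-m) + (2/3)m^2 (see :func:`markerscan.diversity.expected_star_pi`).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ancestor = _random_seq(rng, length)
    records = []
    for i in range(n_sequences):
        seq, _ = _mutate(rng, ancestor, mutation_rate, set())
        records.append(SequenceRecord(id=f"t{i + 1}", seq=seq))
    return SequenceCollection(records=records, aligned=False)


def generate_reads(
    community: MockCommunity,
    marker: str,
    pair: PrimerPair,
    depth_per_strain: int,
    error_rate: float = 0.0,
    seed: int | None = None,
) -> tuple[SequenceCollection, dict[str, str]]:
    """Simulate amplicon reads: full-length product copies with iid base errors.

    Each amplifiable strain contributes ``depth_per_strain`` reads of its
    leftmost in-silico product; strains with no product contribute none.
    Returns the reads and a read_id -> source strain truth mapping.
    """
    if not 0.0 <= error_rate <= 0.05:
        raise SequenceError("error_rate must be in [0, 0.05]")
    from .primers import in_silico_pcr

    rng = np.random.default_rng(seed)
    reads: list[SequenceRecord] = []
    mapping: dict[str, str] = {}
    for strain, markers in community.members.items():
        if marker not in markers:
            raise SequenceError(f"strain {strain!r} lacks marker {marker!r}")
        products = in_silico_pcr(pair, markers[marker])
        if not products:
            continue
        template = products[0].seq
        for k in range(depth_per_strain):
            seq, _ = _mutate(rng, template, error_rate, set())
            rid = f"{strain}.read{k + 1}"
            reads.append(SequenceRecord(id=rid, seq=seq, description=strain))
            mapping[rid] = strain
    return SequenceCollection(records=reads, aligned=False), mapping


# --- synthetic stand-in for the 8-strain mock community -----------------------

#: Strain labels of the 8-member community; the pairs sharing one 16S V3-V4
#: amplicon and the pairs sharing one gyrA amplicon are fixed below
#: (LY37/LY43 stay distinguishable on gyrA although not on 16S).
MOCK_STRAINS = ("LY1", "LY2", "LY18", "LY35", "LY37", "LY39", "LY43", "LY48")
MOCK_16S_TWINS = (("LY1", "LY18"), ("LY37", "LY43"), ("LY39", "LY48"))
MOCK_GYRA_TWINS = (("LY1", "LY18"), ("LY39", "LY48"))


def mock_community_8(seed: int = 0) -> MockCommunity:
    """A synthetic 8-strain community with a known resolution structure.

    This is a synthetic stand-in for a real defined strain mixture: the 16S
    genes of three strain pairs are constructed with identical V3-V4 amplicons
    (5 distinguishable units among 8 members) while their gyrA genes collapse
    only one pair (6 units). All members are amplifiable by the 16S V3-V4 and
    gyrA3 primer pairs by construction.
    """
    from .primers import KNOWN_PAIRS

    rng = np.random.default_rng(seed)
    p16 = KNOWN_PAIRS["16S-V3V4"]
    pgy = KNOWN_PAIRS["gyrA3"]
    mt16 = MarkerTemplate(name="16S", length=1540, pair=p16,
                          fwd_pos=338, rev_pos=785)
    mtgy = MarkerTemplate(name="gyrA", length=2450, pair=pgy,
                          fwd_pos=350, rev_pos=830)

    def base_for(mt: MarkerTemplate) -> str:
        s = _random_seq(rng, mt.length)
        s = _plant_site(s, mt.fwd_pos - 1, min(expand_degenerate(mt.pair.forward)))
        s = _plant_site(s, mt.rev_pos - 1,
                        reverse_complement(min(expand_degenerate(mt.pair.reverse))))
        return s

    base = {"16S": base_for(mt16), "gyrA": base_for(mtgy)}
    templates = {"16S": mt16, "gyrA": mtgy}
    twins = {"16S": MOCK_16S_TWINS, "gyrA": MOCK_GYRA_TWINS}

    members: dict[str, dict[str, SequenceRecord]] = {s: {} for s in MOCK_STRAINS}
    for marker, mt in templates.items():
        span_start, span_end = mt.amplicon_span
        insert0 = set(range(span_start - 1 + len(mt.pair.forward),
                            span_end - len(mt.pair.reverse)))
        outside0 = sorted(set(range(mt.length)) - set(range(span_start - 1, span_end)))
        # unit leader per strain: twins share their leader's insert mutations
        leader = {s: s for s in MOCK_STRAINS}
        for a, b in twins[marker]:
            leader[b] = a
        insert_muts: dict[str, list[tuple[int, str]]] = {}
        for s in MOCK_STRAINS:
            if leader[s] != s:
                continue
            pos = rng.choice(sorted(insert0), size=6, replace=False)
            insert_muts[s] = []
            for p in sorted(int(x) for x in pos):
                old = base[marker][p]
                alt = [b for b in _BASE_STR if b != old][int(rng.integers(0, 3))]
                insert_muts[s].append((p, alt))
        for s in MOCK_STRAINS:
            arr = list(base[marker])
            for p, alt in insert_muts[leader[s]]:
                arr[p] = alt
            # strain-private mutations outside the amplicon keep full genes distinct
            for p in rng.choice(outside0, size=4, replace=False):
                old = arr[int(p)]
                arr[int(p)] = [b for b in _BASE_STR if b != old][int(rng.integers(0, 3))]
            members[s][marker] = SequenceRecord(
                id=f"{s}|{marker}", seq="".join(arr), description=s,
            )
    return MockCommunity(members=members)
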