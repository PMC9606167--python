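"""Degenerate-primer expansion, binding-site search and in-silico PCR.

A degenerate primer written over the IUPAC alphabet represents a mixture of
exact oligonucleotides. A template position is called a binding site when the
best non-degenerate expansion of the primer matches at least ``min_match``
identical bases over the full primer length, with no indels. A template is
amplifiable by a pair when a forward site and a downstream reverse site (on
opposite strands) bracket a product within the configured length bounds.

Matching is done by direct window scanning, which on ungapped windows is
exactly the identical-base criterion; degenerate letters in the *template*
count as mismatches (assembly ambiguity is uncertainty, not a wildcard).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .seqio import (
    IUPAC_CODES,
    SequenceCollection,
    SequenceError,
    SequenceRecord,
    reverse_complement,
)

_ACGT = frozenset("ACGT")


class PrimerError(ValueError):
    """Raised for invalid primer definitions."""


@dataclass(frozen=True)
class DegeneratePrimer:
    """A primer over the IUPAC nucleotide alphabet."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        s = self.seq.upper()
        if not s:
            raise PrimerError(f"primer {self.name!r}: empty sequence")
        bad = set(s) - set(IUPAC_CODES)
        if bad:
            raise PrimerError(
                f"primer {self.name!r}: non-IUPAC character {sorted(bad)[0]!r}"
            )
        object.__setattr__(self, "seq", s)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def degeneracy(self) -> int:
        """Number of exact sequences the primer represents."""
        n = 1
        for c in self.seq:
            n *= len(IUPAC_CODES[c])
        return n


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primer pair plus the amplifiability rule parameters.

    ``min_match`` is an absolute count of identical bases required at each
    primer site (default 18). Product length is bounded by
    ``min_amplicon_len``/``max_amplicon_len`` to exclude degenerate pairings
    spanning most of a genome.
    """

    name: str
    forward: DegeneratePrimer
    reverse: DegeneratePrimer
    min_match: int = 18
    min_amplicon_len: int = 100
    max_amplicon_len: int = 3000

    def __post_init__(self) -> None:
        if not (0 < self.min_match <= min(len(self.forward), len(self.reverse))):
            raise PrimerError(
                f"pair {self.name!r}: min_match {self.min_match} exceeds a primer length"
            )
        if not (0 < self.min_amplicon_len <= self.max_amplicon_len):
            raise PrimerError(f"pair {self.name!r}: bad amplicon length bounds")


@dataclass(frozen=True)
class BindingSite:
    """One primer binding site, in 1-based inclusive + strand coordinates."""

    record_id: str
    strand: str  # '+' or '-'
    start: int
    end: int
    matched: int
    variant: str  # the non-degenerate expansion achieving the match


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product spanning forward-primer start to reverse-primer end."""

    record_id: str
    start: int
    end: int
    seq: str
    pair_name: str
    fwd_len: int = 0
    rev_len: int = 0

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def insert(self) -> str:
        """Product with the two primer-binding regions trimmed off."""
        return self.seq[self.fwd_len:len(self.seq) - self.rev_len]


def expand_degenerate(primer: DegeneratePrimer | str) -> set[str]:
    """All non-degenerate (ACGT) sequences a degenerate primer represents."""
    seq = primer.seq if isinstance(primer, DegeneratePrimer) else DegeneratePrimer("_", primer).seq
    pools = [sorted(IUPAC_CODES[c]) for c in seq]
    return {"".join(p) for p in itertools.product(*pools)}


def match_count(variant: str, window: str) -> int:
    """Identical-base count between an exact primer variant and a template window.

    Template positions holding N or any ambiguity code never count as matches.
    """
    if len(variant) != len(window):
        raise ValueError("variant and window must have equal length")
    return sum(1 for v, w in zip(variant, window) if v == w and w in _ACGT)


def _code_sets(seq: str) -> list[frozenset[str]]:
    return [IUPAC_CODES[c] for c in seq]


def _scan_window(sets: list[frozenset[str]], window: str) -> tuple[int, list[bool]]:
    """Best-over-variants match profile of a degenerate primer at one window.

    Degenerate positions vary independently across expansions, so the best
    expansion matches at exactly the positions where the window base falls in
    the primer's IUPAC set; this is equivalent to (and much cheaper than)
    enumerating every expansion.
    """
    hits = [w in s and w in _ACGT for s, w in zip(sets, window)]
    return sum(hits), hits


def _witness_variant(sets: list[frozenset[str]], window: str, hits: list[bool]) -> str:
    return "".join(w if h else min(s) for s, w, h in zip(sets, window, hits))


def find_binding_sites(
    primer: DegeneratePrimer,
    target: SequenceRecord,
    min_match: int,
    *,
    contiguous: bool = False,
    anchor_3prime: int = 0,
) -> list[BindingSite]:
    """Scan a template for primer binding sites on both strands.

    Every window of primer length on the + strand is compared against the
    expansions of the primer (+ strand sites) and of its reverse complement
    (- strand sites); a site is reported when the best variant matches >=
    ``min_match`` identical bases. No indels inside a site.

    ``contiguous`` additionally requires a run of ``min_match`` consecutive
    identities; ``anchor_3prime`` requires the N 3'-terminal primer bases to
    match exactly. Both default off.
    """
    if "-" in target.seq:
        raise SequenceError(f"target {target.id!r} is gapped; ungapped sequence required")
    k = len(primer)
    tseq = target.seq
    if len(tseq) < k:
        return []
    fwd_sets = _code_sets(primer.seq)
    rev_sets = _code_sets(reverse_complement(primer.seq))

    def ok(hits: list[bool], matched: int, strand: str) -> bool:
        if matched < min_match:
            return False
        if contiguous:
            run = best = 0
            for h in hits:
                run = run + 1 if h else 0
                best = max(best, run)
            if best < min_match:
                return False
        if anchor_3prime:
            # primer 3' end: rightmost window bases on +, leftmost on -
            tail = hits[-anchor_3prime:] if strand == "+" else hits[:anchor_3prime]
            if not all(tail):
                return False
        return True

    sites: list[BindingSite] = []
    for i in range(len(tseq) - k + 1):
        window = tseq[i:i + k]
        m, hits = _scan_window(fwd_sets, window)
        if ok(hits, m, "+"):
            v = _witness_variant(fwd_sets, window, hits)
            sites.append(BindingSite(target.id, "+", i + 1, i + k, m, v))
        m, hits = _scan_window(rev_sets, window)
        if ok(hits, m, "-"):
            # witness reported in primer (not window) orientation
            v = reverse_complement(_witness_variant(rev_sets, window, hits))
            sites.append(BindingSite(target.id, "-", i + 1, i + k, m, v))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def in_silico_pcr(pair: PrimerPair, target: SequenceRecord, **site_kwargs) -> list[Amplicon]:
    """Predict PCR products of a primer pair on one ungapped template.

    A product arises from a forward-primer + strand site paired with a
    downstream reverse-primer - strand site, or mirror-wise from a
    forward-primer - strand site with an upstream reverse-primer + strand
    site. Products are reported in + strand coordinates, ordered by
    (start, end); an empty list means not amplifiable.
    """
    fwd_sites = find_binding_sites(pair.forward, target, pair.min_match, **site_kwargs)
    rev_sites = find_binding_sites(pair.reverse, target, pair.min_match, **site_kwargs)

    out: list[Amplicon] = []
    seen: set[tuple[int, int]] = set()

    def emit(start: int, end: int, plus_orientation: bool) -> None:
        length = end - start + 1
        if not (pair.min_amplicon_len <= length <= pair.max_amplicon_len):
            return
        if (start, end) in seen:
            return
        seen.add((start, end))
        seq = target.seq[start - 1:end]
        if not plus_orientation:
            seq = reverse_complement(seq)
        out.append(Amplicon(
            record_id=target.id, start=start, end=end, seq=seq,
            pair_name=pair.name,
            fwd_len=len(pair.forward), rev_len=len(pair.reverse),
        ))

    for f in (s for s in fwd_sites if s.strand == "+"):
        for r in (s for s in rev_sites if s.strand == "-"):
            if r.start > f.start:
                emit(f.start, r.end, True)
    # mirrored: product read off the - strand
    for f in (s for s in fwd_sites if s.strand == "-"):
        for r in (s for s in rev_sites if s.strand == "+"):
            if r.start < f.start:
                emit(r.start, f.end, False)
    out.sort(key=lambda a: (a.start, a.end))
    return out


@dataclass
class SpeciesAmplifiability:
    species: str
    n_sequences: int
    n_amplifiable: int

    @property
    def amplifiable(self) -> bool:
        return self.n_amplifiable > 0


@dataclass
class AmplifiabilitySummary:
    """Per-species amplifiability table plus database-wide totals."""

    pair_name: str
    rows: list[SpeciesAmplifiability] = field(default_factory=list)

    @property
    def n_sequences_matched(self) -> int:
        return sum(r.n_amplifiable for r in self.rows)

    @property
    def n_species_matched(self) -> int:
        return sum(1 for r in self.rows if r.amplifiable)


def amplifiability_summary(db: SequenceCollection, pair: PrimerPair,
                           **site_kwargs) -> AmplifiabilitySummary:
    """Count, per species, how many database sequences the pair amplifies.

    A species counts as identified iff at least one of its sequences yields at
    least one in-silico product. Every record must carry a taxon label.
    """
    per: dict[str, SpeciesAmplifiability] = {}
    for rec in db:
        if not rec.taxon_label:
            raise SequenceError(f"record {rec.id!r} has no taxon label")
        row = per.setdefault(
            rec.taxon_label, SpeciesAmplifiability(rec.taxon_label, 0, 0)
        )
        row.n_sequences += 1
        if in_silico_pcr(pair, rec, **site_kwargs):
            row.n_amplifiable += 1
    summary = AmplifiabilitySummary(pair_name=pair.name)
    summary.rows = [per[k] for k in sorted(per)]
    return summary


def _pair(name: str, fwd: str, rev: str, **kw) -> PrimerPair:
    return PrimerPair(
        name=name,
        forward=DegeneratePrimer(f"{name}-F", fwd),
        reverse=DegeneratePrimer(f"{name}-R", rev),
        **kw,
    )


#: Published primer pairs for Bacillus gyrA and 16S rRNA amplification.
KNOWN_PAIRS: dict[str, PrimerPair] = {
    "gyrA1": _pair("gyrA1", "CAGTCAGGAAATGCGTACGTCCTT", "GTATCCGTTGTGCGTCAGAGTAAC"),
    "gyrA2": _pair("gyrA2", "CAGTCAGGAAATGCGTACGTCCTT", "CAAGGTAATGCTCCAGGCATTGCT"),
    "gyrA3": _pair("gyrA3", "GCDGCHGCNATGCGTTAYAC", "ACAAGMTCWGCKATTTTTTC"),
    "gyrA4": _pair("gyrA4", "TAYGCRATGAGYRTHATYGT", "TTBGTNGCCATHCCDACMGC"),
    "gyrA5": _pair("gyrA5", "GCDGCNGCVATGCGTTAYAC", "CGNAGRTYBGTAATDCCDTC"),
    "16S-full": _pair("16S-full", "AGAGTTTGATCCTGGCTCAG", "GGTTACCTTGTTACGACTT"),
    "16S-V3V4": _pair("16S-V3V4", "CCTACGGRRBGCASCAGKVRVGAAT", "GGACTACNVGGGTWTCTAATCC"),
}
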