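"""Reference-anchored variable-site and per-genome SNP-frequency profiling.

Each genome in an aligned collection is compared column-by-column against one
representative (reference) sequence inside a fixed sub-region of the marker.
A mismatch is recorded where both the genome and the reference carry a
concrete base (A/C/G/T) and the bases differ; gap or ambiguous columns are
skipped for that genome but the frequency denominator stays the fixed region
length, so per-genome SNP frequencies are directly comparable across genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .seqio import SequenceCollection, SequenceError

_ACGT = frozenset("ACGT")

EN_DASH = "–"


@dataclass(frozen=True)
class GenomeMismatch:
    genome_id: str
    n_mismatches: int
    freq_pct: float  # 100 * n_mismatches / region_length, full precision


@dataclass
class VariableSiteProfile:
    """Variable sites of one marker region, anchored to a reference genome."""

    gene_label: str
    region: tuple[int, int]          # 1-based inclusive alignment columns
    region_length: int               # denominator for frequencies
    reference_id: str
    variable_sites: list[int]        # absolute alignment columns, sorted
    per_genome: list[GenomeMismatch]
    n_genomes_total: int
    species: str = ""

    @property
    def n_variable_sites(self) -> int:
        return len(self.variable_sites)

    @property
    def n_genomes_variable(self) -> int:
        return sum(1 for g in self.per_genome if g.n_mismatches >= 1)

    @property
    def mismatch_range(self) -> tuple[int, int]:
        """(min, max) mismatch count over genomes with >=1 mismatch; (0, 0) if none."""
        counts = [g.n_mismatches for g in self.per_genome if g.n_mismatches >= 1]
        if not counts:
            return (0, 0)
        return (min(counts), max(counts))

    @property
    def freq_range_pct(self) -> tuple[float, float]:
        lo, hi = self.mismatch_range
        return (100.0 * lo / self.region_length, 100.0 * hi / self.region_length)


def choose_reference(alignment: SequenceCollection,
                     reference_id: str | None = None) -> str:
    """The configured reference id if given (must exist), else the first record."""
    if not len(alignment):
        raise SequenceError("empty collection")
    if reference_id is None:
        return alignment.records[0].id
    if reference_id not in alignment.ids:
        raise SequenceError(f"reference {reference_id!r} not in collection")
    return reference_id


def variable_sites(
    alignment: SequenceCollection,
    reference_id: str | None = None,
    region: tuple[int, int] | None = None,
    *,
    gene_label: str = "",
    species: str = "",
    region_length: int | None = None,
) -> VariableSiteProfile:
    """Profile mismatches of every genome against the reference in a region.

    ``region`` is 1-based inclusive alignment columns (default: full
    alignment). ``region_length`` overrides the frequency denominator when the
    nominal region length differs from the column span (e.g. a region quoted
    as 480 bp spanning 481 columns).
    """
    if not alignment.aligned:
        # gap-free equal-length collections count as aligned for this purpose
        lengths = {len(r) for r in alignment}
        if len(lengths) != 1:
            raise SequenceError("variable_sites requires an aligned collection")
    length = len(alignment.records[0].seq)
    if region is None:
        region = (1, length)
    start, end = region
    if not (1 <= start <= end <= length):
        raise SequenceError(f"region {start}-{end} outside alignment of length {length}")
    if region_length is None:
        region_length = end - start + 1

    ref_id = choose_reference(alignment, reference_id)
    ref = alignment[ref_id].seq[start - 1:end]

    site_cols: set[int] = set()
    per_genome: list[GenomeMismatch] = []
    for rec in alignment:
        if rec.id == ref_id:
            continue
        sub = rec.seq[start - 1:end]
        n = 0
        for i, (g, r) in enumerate(zip(sub, ref)):
            if g in _ACGT and r in _ACGT and g != r:
                n += 1
                site_cols.add(start + i)
        per_genome.append(GenomeMismatch(rec.id, n, 100.0 * n / region_length))

    return VariableSiteProfile(
        gene_label=gene_label,
        region=(start, end),
        region_length=region_length,
        reference_id=ref_id,
        variable_sites=sorted(site_cols),
        per_genome=per_genome,
        n_genomes_total=len(alignment),
        species=species,
    )


def _round_half_up(x: float, places: int = 2) -> str:
    q = Decimal(1).scaleb(-places)
    return str(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SpeciesRow:
    """One polymorphism-summary row for a (species, gene) pair."""

    species: str
    gene: str
    gene_length: int
    n_variable_sites: int
    n_genomes_total: int
    n_genomes_variable: int
    mismatch_range: str   # e.g. "1–7"
    freq_range_pct: str   # e.g. "0.21–1.46"


def summarize_species(profiles: list[VariableSiteProfile]) -> list[SpeciesRow]:
    """Render profiles as polymorphism-summary rows (en-dash ranges, 2-decimal %)."""
    if not profiles:
        raise SequenceError("no profiles to summarise")
    rows = []
    for p in profiles:
        lo, hi = p.mismatch_range
        flo, fhi = p.freq_range_pct
        rows.append(SpeciesRow(
            species=p.species,
            gene=p.gene_label,
            gene_length=p.region_length,
            n_variable_sites=p.n_variable_sites,
            n_genomes_total=p.n_genomes_total,
            n_genomes_variable=p.n_genomes_variable,
            mismatch_range=f"{lo}{EN_DASH}{hi}",
            freq_range_pct=f"{_round_half_up(flo)}{EN_DASH}{_round_half_up(fhi)}",
        ))
    return rows
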