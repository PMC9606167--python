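# Methods

`markerscan` evaluates a candidate marker gene and its degenerate primer pair
for genus-level community profiling. Four analysis stages share one sequence
model (`seqio`): in-silico PCR (`primers`), sliding-window nucleotide
diversity (`diversity`), reference-anchored SNP profiling (`snp`) and
mock-community resolution (`resolution`). A synthetic genus generator
(`synthetic_data`) provides inputs with known truth for every stage.

## In-silico PCR and the minimum-match rule

A degenerate primer over the IUPAC alphabet denotes the set of its
non-degenerate expansions (cardinality = product of per-position
degeneracies; e.g. the gyrA3 forward primer GCDGCHGCNATGCGTTAYAC expands to
3·3·4·2 = 72 exact 20-mers). A template window of primer length is a binding
site when the best expansion matches at least `min_match` identical bases
(default 18), with no indels permitted inside the site. Because degenerate
positions expand independently, the best-over-expansions match count equals
the number of window positions whose base lies in the primer's per-position
IUPAC set; the scanner exploits this identity, and the test suite checks it
against brute-force enumeration of all expansions.

Choices on points the matching rule leaves open:

- **Non-contiguous matches count.** The rule is "≥ min_match identical
  positions over the full primer length"; the identities need not be
  consecutive, since such thresholds are typically applied to local-alignment
  hits. `contiguous=True` and `anchor_3prime=N` are available for sensitivity
  analysis (both strictly reduce the site set).
- **Template ambiguity codes never match.** In an assembly, N or R means
  uncertainty, not a wildcard; counting it as a match would overstate
  amplifiability.
- **Product length bounds** default to 100–3000 bp. They are not part of the
  matching rule; they exclude pathological pairings of distant sites on a
  genome-length template and are configurable per `PrimerPair`.
- `min_match` is an absolute base count, not a fraction, so a 24-nt primer is
  allowed 6 mismatches where a 20-nt primer is allowed 2.

A template is amplifiable when a forward site and a downstream
reverse-primer site on the opposite strand bracket a product within the
length bounds; the strand-mirrored configuration is reported in plus-strand
coordinates. A species counts as detected by a pair if at least one of its
sequences yields at least one product.

Caveat: because indels inside a primer site are forbidden, site counts may
differ from workflows that accept gapped alignment hits.

## Nucleotide diversity

π is the mean over all n(n−1)/2 unordered sequence pairs of
(pairwise differences / pairwise valid sites). A site is valid for a pair
when both sequences carry a concrete base (A/C/G/T); gaps and ambiguity codes
are treated as missing. This is **pairwise deletion**; since diversity tools
differ in their missing-data rule, `deletion="complete"` (drop any column
with missing data in any sequence) is also provided. Pairs with zero valid
sites are excluded from the mean; if all pairs are excluded the result is
NaN.

The sliding-window profile uses window 100 bp and step 10 bp by default,
windows defined on alignment columns (gap columns inside the span count
toward the span, not toward valid sites). The reported midpoint is
`start + window/2 − 1` by default; published profiles sometimes use other
plotting offsets, so the offset is configurable (`midpoint_offset`).

For validation, the star-topology generator gives an analytic target: if two
sequences are independent per-site mutants of one ancestor with substitution
probability m (mutant base uniform over the 3 alternatives), they differ at a
site with probability 2m(1−m) + (2/3)m², which is the expected π of the
sample. The suite checks recovery at m = 0.02, 10 sequences × 500 nt,
200 replicates, within 3 Monte-Carlo standard errors — sizes chosen so the
Monte-Carlo error is a few percent of the target while the check runs in
seconds.

## SNP profiling

Within a fixed marker sub-region (1-based inclusive alignment columns, e.g.
330–810 for a 16S V3-V4 segment or 350–850 for a gyrA amplicon region), each
genome is compared column-by-column to one representative (reference)
sequence — a configured id, else the first record. A mismatch requires
concrete differing bases in both sequences; a variable site is any column
where at least one genome mismatches the reference.

Two deliberate conventions:

- **Fixed denominator.** Gap/ambiguous columns are skipped for a genome's
  comparison but the per-genome SNP frequency divides by the *fixed* region
  length (overridable via `region_length`, e.g. 480 for a region spanning 481
  columns when the nominal amplicon length is 480 bp). This keeps
  frequencies comparable across genomes: 1 mismatch in a 480-bp region is
  always 0.21%.
- **Gap-vs-base columns are not variable sites.** Indel polymorphism is out
  of scope; only substitutions are counted.

Summary rows render mismatch-count and frequency ranges over genomes with at
least one mismatch, frequencies rounded half-up at 2 decimals with an
en-dash between bounds.

## Mock-community resolution

Each community member's marker sequence is amplified in silico; members whose
products are string-identical are indistinguishable and merge into one unit.
Identity is judged on the amplicon **insert** (primer-binding regions
trimmed) because sequenced products of degenerate primers carry
primer-encoded variation that is not biological; `keep_primers=True`
restores full-product comparison. When a member yields several products the
leftmost is used, deterministically; `unamplified` members form their own
reported group outside the unit count.

The simulated-read workflow mirrors a denoising pipeline on error-containing
reads: exact dereplication stands in for denoising (adequate because the
simulator emits substitution errors only), unique sequences are annotated to
the per-strain reference amplicons by ungapped end-trimmed global identity
(default threshold 0.97), ties go to `unassigned`, and read counts are pooled
per resolved unit with total-count conservation. The tie rule means reads
from strains with identical reference amplicons are never force-assigned to
either strain; unit merging then reports them jointly, which reproduces
printed unit counts without guessing within-pair assignments.

## Synthetic data generator

The generator emulates a genus sampled through marker genes:

- **Star phylogeny.** One genus ancestor per marker; species ancestors are
  independent per-site mutants of it (`interspecies_divergence`, default
  0.15 substitutions/site); strains are independent mutants of their species
  ancestor (`intraspecies_rate`, default 0.02). These defaults put
  within-species diversity near a few percent and between-species divergence
  an order of magnitude higher — the regime in which a protein-coding marker
  out-resolves a slowly evolving rRNA gene.
- **Planted primer sites.** Each marker template embeds one exact expansion
  of the forward primer and the reverse complement of one expansion of the
  reverse primer; mutations are never planted inside these sites for
  compatible genomes, so amplifiability is known by construction. Deliberately
  incompatible species have every primer-site position flipped to a base
  outside the primer's IUPAC set, so no expansion can match anywhere near the
  threshold.
- **Substitutions only.** Mutant bases are uniform over the 3 alternatives;
  no indels are generated, so per-marker collections are equal-length and
  gap-free and feed the diversity/SNP modules without an aligner. Gap
  handling is exercised separately by hand-built gapped fixtures in the
  tests.
- **Multi-copy loci.** A marker with `copies > 1` emits extra per-genome
  copies mutated at `copy_snp_rate`, emulating rRNA operon heterogeneity.
- **Reads.** Simulated reads are full-length amplicon copies with iid
  substitution errors at `error_rate` (≤ 0.05); a truth mapping records each
  read's source strain.

`mock_community_8` is a **synthetic stand-in** for a defined 8-strain
mixture: strains LY1/LY18, LY37/LY43 and LY39/LY48 are built with identical
16S V3-V4 amplicons (5 distinguishable units among 8 members) while on gyrA
only LY1/LY18 and LY39/LY48 collapse (6 units), with LY37/LY43 separated.
Outside the amplicons every strain carries private mutations, so full genes
are all distinct.

What passing on synthetic data does **not** show: robustness to indels and
alignment error, chimeras, quality-dependent sequencing error, primer-bias
abundance distortion, or real taxonomic structure deeper than a two-level
star phylogeny. Results on real genome databases additionally depend on the
external aligner and on database composition.

## Numerical and interface choices

- Coordinates are 1-based inclusive at every user-facing interface, 0-based
  half-open internally; a region a–b therefore spans b−a+1 columns (330–810 →
  481). When a nominal region length differs (a "480 bp" region), the
  frequency denominator is set explicitly.
- `U` is normalised to `T`, `.` to `-`; sequences are validated against the
  IUPAC alphabet on ingest with the offending record and character named.
- All randomness flows through `numpy.random.default_rng` seeds; identical
  seeds give byte-identical FASTA, truth tables and reports.
- Reports are TSV with a header row and explicit float precision; every CLI
  run writes a JSON manifest of its parameters for reproduction.

## Known limitations

- No thermodynamics: primer matching is purely combinatorial; melting
  temperature, 3′ stability and secondary structure are ignored.
- No gapped primer hits; no indel calling; no chimera model.
- π confidence intervals, Watterson's θ and Tajima's D are out of scope.
- ZOTU annotation uses ungapped end-trimmed identity, which assumes
  length-conserved amplicons (true for the simulator's reads).
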