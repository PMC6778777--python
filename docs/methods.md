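# Methods

## The inference

The package infers the heterogametic sex of a species from reduced
representation sequencing of a known-sex cohort, without any reference
genome. The object of inference is a set of loci carried only on the
sex-limited chromosome (W under female heterogamety, Y under male
heterogamety). Such a locus is (a) present in every individual of the
heterogametic sex and absent from the other sex, (b) hemizygous — at most
one haplotype per carrier — and (c) sequenced at roughly half the depth of
a diploid locus. The three filters are applied in that order and nest by
construction; because ZW and XY are mutually exclusive, candidates under
the wrong hypothesis co-amplify in both sexes when screened by PCR, which
is what the decision stage formalises. The method is deterministic set
logic, not a statistical test: there is no p-value, and its error modes
are coverage artifacts (false presence/absence patterns), which the
saturation analysis and the depth filter are designed to expose.

The presence rule is strict (all of one sex, none of the other) by
default. A relaxed mode (`min_presence_frac < 1`) requires presence in
only a fraction of the carrying sex while keeping absence in the other sex
absolute; it buys sensitivity under very uneven coverage at the cost of
spurious candidates, and is off by default. Sexes must be known with
certainty: a single mislabelled individual silently destroys true
candidates (strict rule) or manufactures conflicts, and the matrix
constructor refuses unknown sex labels outright.

## Simulated study design

The synthetic-data generator emulates the ddRAD design the method is used
with in practice:

- **Digestion.** Two enzymes modelled as recognition site + cut offset:
  SphI (GCATG^C, offset 5) at the 5' end and EcoRI (G^AATTC, offset 1) at
  the 3' end. Cuts are placed on the + strand at every site occurrence;
  fragments partition the input, and each fragment's ends carry the enzyme
  identity. Size selection retains only correctly oriented SphI→EcoRI
  fragments in a 450–550 bp window — the strand-specific library chemistry
  cannot amplify single-enzyme or reversed fragments.
- **Loci.** Each planted locus is a digest fragment (5' remnant +
  site-free core + 3' remnant), uniform in length over the window (the
  empirical in-window length distribution is unknown; uniform is the
  neutral choice). Chromosome classes: autosome (2 copies in everyone),
  shared sex chromosome Z/X (1 copy in the heterogametic sex, 2 in the
  other), sex-limited W/Y (1 copy in the heterogametic sex only).
  Sex-limitation is modelled as sequence absence, not cut-site
  polymorphism. Autosomal and shared loci acquire a second allele by
  per-base mutation at `snp_rate` (default 0.002/bp); allele copies
  segregate at frequency ½. Two generation-time guards keep the planted
  truth recoverable: alleles of one locus differ at ≤ 4 read-visible
  positions (a heterozygote must assemble as one locus under the default
  mismatch limit M = 4), and alleles of different loci differ at ≥ 5
  read-visible positions (distinct loci must not merge). Colliding loci
  are redrawn.
- **Reads.** Paired-end 150 bp: R1 = 5 bp inline barcode + the locus 5'
  prefix; R2 = reverse complement of the locus 3' suffix. Stitched reads
  (R1 + revcomp R2, barcode trimmed) are therefore a fixed 295 bp view of
  each locus with the middle unsequenced. Substitution errors are applied
  per base at the individual's `error_rate`; base qualities are a
  configured constant (Phred 37 by default — quality miscalibration is not
  modelled). Barcodes are generated at pairwise Hamming distance ≥ 3 so
  single-error reads still demultiplex uniquely. Read names carry the
  source locus and allele for truth-tracking only; no analysis code reads
  them.
- **Depth.** Each individual yields exactly `target_read_pairs` pairs,
  allocated across its locus copies by a multinomial draw, so per-copy
  counts are approximately Poisson and a hemizygous locus receives half
  the expected depth of a diploid one automatically. Between-individual
  variation in library yield — the dominant source of depth variation in
  real cohorts — is modelled by varying `target_read_pairs` (or the
  per-individual `mean_depths` argument of `make_cohort`). Optional
  within-individual overdispersion is available by setting
  `depth_dispersion` (gamma-weighted multinomial, NB-like marginals);
  it is off by default because the exact-total contract is what ties the
  simulator to the demultiplexing accounting, and the extra dispersion has
  no separate empirical anchor once library yield is modelled explicitly.

What the simulator does **not** model — and hence what passing tests do
not establish about real data: repeat and transposon content (real
catalogs are contaminated by repeat-derived loci far beyond what the
depth-outlier filter sees here), indels and gapped alignment, PCR
duplicates, restriction-site polymorphism as a sex-linkage mechanism,
population structure (allele frequencies are fixed at ½), linked variation
between loci, and quality-score miscalibration.

## Read processing

Stitching concatenates R1 with the reverse complement of R2, restoring
fragment orientation; it is an exact involution (split + re-complement
recovers the pair). Demultiplexing assigns a read to the unique barcode
within `max_barcode_mismatch` (default 1) Hamming distance of its first
five bases; ties and misses go to "unassigned". The quality filter slides
a window of `round(0.15 × read length)` bases (45 bp for a 300 bp stitched
read) one base at a time and keeps a read only if every full window's mean
Phred is strictly greater than 20; trailing partial windows are not
evaluated. The window is sized from the untrimmed stitched read and the
filter applied before barcode trimming. Cut-site verification is an exact
string match on the enzyme remnants at both ends of the trimmed read; no
rescue of mutated sites is attempted.

## Assembly

A deliberately simplified, fully deterministic re-implementation of the
stack/catalog workflow, not a port: identical reads form stacks; stacks
with depth ≥ m (default 3) are primary; primaries at Hamming distance ≤ M
(default 4) are linked and connected components become loci; components
joining more than two primaries are blacklisted as putative repeats;
remaining low-depth reads add depth to the unique locus whose consensus is
within N (default 10) mismatches, ambiguous reads to none. Alleles are the
primary-stack sequences themselves — there is no model-based SNP calling —
and the consensus is the depth-weighted per-column majority with ties
broken A<C<G<T. Gapped alignment and statistical paralog tests are out of
scope. A per-individual depth filter removes loci deeper than
mean + 3 SD (sample SD, computed once before removal), the standard guard
against collapsed repeats.

The catalog merges per-individual loci across the cohort. With the default
catalog mismatch n = 0, merging is by consensus identity — an equivalence
relation, so the catalog is invariant to individual order, and ids are
assigned from the sha1 order of consensus sequences for determinism. The
identity rule has a consequence worth understanding: a polymorphic locus
whose individuals are fixed (or depth-majority) for different alleles
fragments into several catalog entries with partial membership. This
matches how n = 0 behaves on real data (catalogs several-fold larger than
per-individual locus counts) and is deliberately retained: those fragments
are exactly the spurious sex-specific candidates whose decay the
saturation analysis measures. n > 0 is supported as a greedy merge with an
explicit order-dependence warning.

## Depth normalisation and the ratio window

The depth filter needs a per-individual scale. It uses the median depth
over non-candidate loci present in the individual (requiring ≥ 50 such
loci, configurable), which is robust both to the depth-outlier tail and to
catalog fragmentation. The acceptance window on the carrier mean of
normalised depth is (0.3, 0.7) around the hemizygous expectation of 0.5 —
wide enough for Poisson noise at realistic depths, narrow enough to reject
the autosomal ratio of 1.0. The window is a declared parameter, logged
with every run, not an estimate.

## Saturation

For each replicate a random permutation of each sex is drawn once and
prefixes of length n = 1, 2, 4, 8 are scanned, so subsets are nested and
counts are non-increasing within a replicate by the set-intersection
property (this is also property-tested). Under shallow, polymorphic
conditions the spurious candidate count drops steeply — several-fold per
doubling of individuals — while planted truth persists; the package
reports the replicate table, the mean summary and a log-scale plot.

## Panel decision and sex assay

Marker classification excludes individuals whose positive control (18S)
failed, rather than scoring them as non-amplifying. A marker is
female-specific only if it amplified in all evaluable females and no
evaluable males (mirrored for male-specific); amplification in both sexes
is co-amplifying; none, or partial amplification within a single sex, is
"failed" (unusable as a sex marker — the four-way classification has no
finer bucket, a deliberate simplification). The verdict rule: ≥ 1
female-specific and 0 male-specific ⇒ ZW; mirrored ⇒ XY; neither ⇒
inconclusive; both ⇒ conflict (mislabelled samples or a non-standard
system). The sex assay returns female on any amplifying W marker (flagging
discordant marker sets for retest), male on none — with the documented
caveat that primer-site mutation mimics maleness, the reason multiple W
markers plus a control are used. BatchPrimer3-style primer-design settings
are recorded as constants for documentation export; primer design itself
is not implemented.

## Numerical and scale choices

All intervals are 0-based half-open. Phred encoding is +33 throughout.
Every stochastic step flows from a single integer seed through
`numpy.random.default_rng`; pipeline reruns are byte-identical (gzip
streams are written with a fixed mtime). The bundled default study — 8
females + 8 males, 200 autosomal + 5 W loci, 15 read pairs per locus copy,
error 0.001 — is sized so a full discovery run takes a few seconds and a
20-seed replicate study about two minutes on one CPU; these are the
problem sizes the tests and the acceptance script use. The per-seed
probability of perfect recovery is intrinsically below 1: a W locus is
lost whenever some female draws fewer than three error-free copies of it
(≈ 10⁻³ per locus-female at depth 15 and error 0.001), which is a property
of the method's presence rule, not of the implementation.

## Known limitations

- Absence is confounded with low coverage; the strict presence rule makes
  the method conservative, and the optional `min_presence_depth` and
  relaxed-presence knobs trade that conservatism explicitly.
- The assembler's allele model (primary stacks only) cannot represent
  >2 alleles except by blacklisting, and has no indel tolerance.
- The n = 0 catalog fragments polymorphic loci (see above); downstream
  logic treats fragments as independent loci, which inflates presence-stage
  candidate counts at small cohort sizes.
- The depth filter assumes enough autosomal loci per individual to anchor
  the median; very small panels must lower `min_autosomal_loci`
  consciously.
- Real-data effects outside the simulator's scope (repeats, indels,
  batch effects) are untested here by construction.
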