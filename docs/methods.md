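# Methods

## The analysis in brief

Each transcript in a catalog is annotated with its sAUG (the AUG at the
annotated CDS start) and its fdAUG (the first AUG strictly downstream of
the sAUG whose codon fits entirely within the CDS, `p + 3 ≤ cds_end`;
AUGs overlapping the sAUG are legal hits). The fdAUG frame is
`(fdAUG − sAUG) mod 3`; the spacer is the A-to-A distance in nucleotides,
so `frame ≡ spacer (mod 3)` holds exactly. Stop-distance searches run in
the start's own frame to the end of the *transcript*, not the CDS, because
out-of-frame nested ORFs may terminate inside the 3′ UTR; the reported
length excludes the stop codon itself. Coordinates are 0-based half-open
internally; only rendered reports use 1-based positions.

Catalog filtering applies, in order: CDS length divisible by 3 (curated
records; anything else is malformed input), AUG at the CDS start, ≥6 nt of
upstream flank (required by the context window), an fdAUG present within
the CDS, then per-gene deduplication: isoforms whose sequence stretch from
6 nt upstream of the sAUG through 15 nt past the end of the fdAUG codon is
identical are collapsed to the longest (ties broken by lexicographically
smallest id, for determinism). Every input transcript is either kept or
logged with exactly one rejection reason.

## Context strength

A Kozak context is the 11-mer over positions −6..−1, +1..+3 (the AUG), and
+4..+5. Contexts are keyed in the RNA alphabet; DNA input is silently
normalized (mRNA catalogs are distributed with T). Measured TIE tables are
TSVs of `context → efficiency`; a lookup miss is a first-class value
(`None`), never a silent zero, so filtering stages can count misses — how
missing measured contexts were originally handled is not documented
anywhere we know of, so callers decide whether to drop them.

The synthetic TIE model is multiplicative: `TIE = base · Π w[pos][nt]`
over the eight flank positions, with `base = 150` and weights chosen so
that (a) the arg-max set is exactly the degenerate optimum `RYMRMVAUGGC`
(verified by exhaustive enumeration of all 4⁸ flanks) and (b) the −3 and
+4 positions carry the widest dynamic range (0.45–1.0 and 0.6–1.0),
reflecting their dominant experimental effect. The numeric weights are a
design choice, not measurements; they are config-overridable. Under the
defaults TIE spans [10.58, 150].

## Cohorts and tests

Strong/weak cohorts are the top and bottom `fraction` (default 10%) of
annotated transcripts by sAUG TIE. The cohort size rounds
`fraction · N` to nearest, half away from zero — the only rule consistent
with an 18,297-transcript catalog yielding 1830 per decile. Selection is a
pure function of (TIE, transcript id): both cohorts are slices of one
canonical ordering (TIE descending, id ascending), which also keeps them
disjoint under ties.

Statistical choices, where the convention was genuinely open:

* The frame-0 contrast is a 2×2 chi-squared (frame 0 vs not, strong vs
  weak) without continuity correction; a 2×3 test would dilute the single
  contrast of interest. Expected cells below 5 set a warning flag.
* Rank-sum tests are two-sided Mann–Whitney: exact null distribution when
  both sides have ≤50 observations and no ties; otherwise the normal
  approximation with tie correction and *no* continuity correction (the
  uncorrected approximation keeps null p-values uniform, which the
  calibration tests verify: KS distance from U(0,1) ≈ 0.03 over 1,000
  replicates). Fully tied inputs return p = 1.
* The fdAUG-context comparison uses Welch's unequal-variance t-test;
  cohort variances are not known to be equal.
* Distance comparisons on `fd_stop_nt` exclude unterminated ORFs and count
  the exclusions. Rank tests are invariant to log-transformation, so only
  plots use log₁₀ axes.

## TIESS

`TIESS = Σᵢ log₁₀(TIEᵢ / T̄IE)` over the orthologs *i* of a gene whose
aligned start context yields a TIE; T̄IE is the arithmetic mean TIE (of
TIE, not of log TIE) over every scoreable (gene, species) start context in
the collection, reference species included (`--exclude-reference`
available). An ortholog contributes only with an intact AUG and an
ungapped 11-mer context; otherwise it is skipped and excluded from
`n_orthologs`. A panel with no scoreable entry is absent, not zero —
zero is a meaningful score (consistently average context). The raw sum is
the score; because its magnitude grows with ortholog count, the
per-ortholog mean deviation is reported alongside as a diagnostic.
`--min-orthologs` (default 1) gates scoring. Exact identities used as
tests: duplicating a panel doubles the score; replacing each TIEᵢ by
T̄IE²/TIEᵢ negates it; species order is irrelevant.

## Metagene

Footprint tracks are per-nucleotide counts in transcript coordinates with
footprints already assigned to A-site (elongating) or P-site (initiating)
codons. Inclusion requires CDS ≥ 200 nt, ≥ 200 footprints, and a ≥ 45-nt
5′ leader (sAUG anchor) or a spacer strictly greater than 40 nt (fdAUG
anchor, so the upstream window is not contaminated by sAUG initiation).
Counts are binned into codons phased from the anchor AUG (offset 0 = the
anchor codon; the phasing convention was open and is fixed here), and each
transcript is normalized by its mean CDS counts per codon, so 1 means
average CDS density; per-transcript normalization and codon binning
commute under these conventions. Normalizing twice is a no-op and scaling
a track by any positive constant changes nothing. Zero-count CDSs are
excluded with a reason (the normalization is undefined). Profiles are
per-offset medians with a configurable minimum number of contributing
transcripts (default 1). Window densities are per-transcript means over
the closed windows −15..−3 and +10..+44 codons; window comparisons are
rank-sum tests on the per-transcript means merged across genes — the
per-transcript-first reading keeps transcripts exchangeable units.
Initiating-mode tracks additionally report the offset-0 peak density,
which is the informative quantity for P-site data.

The per-transcript `step_change` (downstream/upstream window ratio, both
anchored at the fdAUG) is the specified diagnostic, but a mean of
per-transcript ratios is biased upward at low coverage (the upstream
window holds ~10 counts at 0.5 reads/nt, and E[1/X] inflation for a
Poisson denominator is then ≈ +12%). Cohort-level recovery therefore uses
`pooled_step_change`, the ratio of across-transcript mean window
densities, which is consistent; at depth 0.5 over 500 transcripts it
recovers a true ratio of 2.0 to within ~1%.

## Synthetic data

The generator emulates the statistical structure the analysis assumes; its
defaults are the study conditions the tests run under.

* **Classes and frames.** Each gene is weak with probability `p_weak`
  (default 0.5). fdAUG frames are class-conditional with defaults
  `p(frame 0 | weak) = 0.524`, `p(frame 0 | strong) = 0.380` (the
  catalog-level proportions used as generator settings) and frame 2
  depleted (0.096 / 0.113) — structurally, an A after a frame-2 fdAUG
  spells UGA in frame 0, so frame-2 fdAUGs are disfavored in stop-free
  CDSs. Frame and spacer are drawn once per gene; structural rejections
  resample only sequence content, so the class-conditional frame and
  spacer laws are exact (whole-gene resampling would deplete frame 2 and
  bias the frame-0 proportions, which the recovery tests would catch).
* **Sequences.** An AUG-free leader of ≥45 nt (drawn 45–75), a CDS whose
  start context is sampled from the strong (top decile) or weak (bottom
  decile) stratum of the synthetic TIE distribution, exactly one
  engineered fdAUG at the drawn spacer (geometric, class means 60/90 nt,
  minimum 4, congruent to the frame) with no earlier accidental AUG
  (enforced by local violation repair, which converges regardless of
  spacer length), 50–90 codons of tail, a terminal stop, and a 20–60 nt
  3′ UTR. Ground truth (contexts, TIEs, fluxes) is extracted from the
  assembled sequence, so annotation round-trips it exactly.
* **Ortholog panels.** Each of S species (default 50) keeps a context from
  the gene's class stratum with probability c (default 0.9), else draws
  from the background context distribution; entries become NA at a small
  rate (default 0.02).
* **Footprints.** P(initiate) = min(1, TIE/TIE_ref) with TIE_ref = 150 (the
  weight-model base, so the optimal context initiates with probability 1);
  the fdAUG flux is (1 − P_init(sAUG)) · P_init(fdAUG). Elongating-mode
  expected density is depth · flux_s between the starts and
  depth · (flux_s + flux_fd) from the fdAUG to the fdAUG-frame stop;
  initiating mode puts point masses at the two start codons
  (depth · 20 · flux per nt) over a 1% background. Counts are independent
  Poisson draws per nucleotide (negative-binomial overdispersion is not
  modeled by default: aggregated multi-study data pin down no single noise
  law, and Poisson keeps expectations analytic). Test scenarios may
  override P_init directly (`p_init_saug_override`, `p_init_fd_override`)
  to realize exact flux ratios.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: uORFs and upstream AUGs in leaders, non-AUG
starts, reinitiation and ribosome queueing, codon-level periodicity and
ligation biases in footprints, transcript-abundance variation, alignment
errors and gaps in ortholog panels beyond the NA rate, and phylogenetic
non-independence of species (every ortholog is drawn independently; no
branch-length weighting).

## Problem sizes used by the test and acceptance runs

Frame-enrichment recovery: 20 fixed seeds × 4,000 genes, cohorts at
fraction 0.5 (the generator's class fraction, so cohorts coincide with the
generating classes at n = 2,000/side); the chi-squared must reject at
p < 10⁻³ in ≥19/20 seeds, and the 40 per-seed 95%-CI coverage checks may
fail at most 6 times (one-sided binomial bound under nominal coverage —
a per-run conjunction of two 95% events is itself only a ~90% event, so
coverage is asserted at the ensemble level). TIESS recovery: 500
conserved-weak (c = 0.9, bottom-quintile stratum) vs 500 background genes
at S = 50, AUROC ≥ 0.95. Metagene recovery: 500 transcripts at depth 0.5
reads/nt, pooled step change within ±10% of 2.0; 300 transcripts/side for
the window contrast. Null calibration: 1,000 rank-sum replicates at
60/side.

## Known limitations

* The synthetic TIE weight model reproduces the published optimum and the
  −3/+4 dominance but not measured efficiency values; analyses of real
  catalogs should supply a measured table.
* TIESS treats species as exchangeable; closely related species inflate
  `n_orthologs` without adding independent evidence.
* The deduplication stretch endpoint ("15 nt downstream from the fdAUG")
  is read as 15 nt past the fdAUG codon's end; the alternative (15 nt past
  the A) differs only for isoforms diverging in exactly that 3-nt window.
* fdAUGs overlapping the annotated stop codon are excluded
  (`p + 3 ≤ cds_end`), the strictest reading of "within the CDS".
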