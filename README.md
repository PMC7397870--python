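# kozakscan

Tools for studying how the strength of an mRNA's annotated start codon
(sAUG) Kozak context relates to the position and reading frame of the first
downstream AUG (fdAUG), for computational biologists working on translation
initiation and leaky scanning.

Scanning preinitiation complexes recognize AUG codons stochastically: when
the sAUG sits in a weak Kozak context (the 11-mer covering positions
−6..−1, the AUG, and +4..+5; +1 is the A of AUG), a fraction of ribosomes
scans past and can initiate at the fdAUG. An in-frame fdAUG then yields an
N-terminally truncated proteoform; an out-of-frame fdAUG yields an
unrelated, typically wasteful, nested ORF. `kozakscan` implements the
catalog-level analyses this hypothesis predicts:

* **Catalog annotation** — parse transcripts (FASTA + CDS TSV), apply
  catalog construction filters (AUG at the CDS start, ≥6 nt upstream flank,
  an fdAUG within the CDS, per-gene isoform deduplication), and annotate
  each transcript with fdAUG position, frame (`(fdAUG − sAUG) mod 3`),
  spacer, stop distances, and context strengths.
* **Context strength (TIE)** — translation initiation efficiency per 11-nt
  context, from a measured lookup table or from a deterministic
  multiplicative position-weight model whose optimum is exactly the
  degenerate pattern `RYMRMVAUGGC`.
* **Cohort statistics** — strong/weak sAUG-context deciles and the frame
  proportion, distance, nested-ORF-length, and fdAUG-context comparisons
  (chi-squared, Mann–Whitney, Welch).
* **Conservation (TIESS)** — the Translation Initiation Efficiency
  Selection Score over ortholog context panels,

  TIESS = Σᵢ log₁₀(TIEᵢ / T̄IE),

  summing over orthologs i, where T̄IE is the mean TIE over all scoreable
  start contexts; far-from-zero scores mark contexts whose strength deviates
  from average consistently across species.
* **Metagene analysis** — per-transcript-normalized ribosome footprint
  densities (1 = mean CDS codon density), anchor-aligned median profiles,
  and upstream (−15..−3 codons) / downstream (+10..+44 codons) window
  density comparisons around sAUG or fdAUG.
* **Proteoform support** — in-silico tryptic digestion and classification
  of peptides as unique to the long (sAUG) proteoform or shared with the
  truncated (fdAUG) proteoform, with observation-frequency summaries.
* **Synthetic data** — a generator that emulates all of the above with
  ground truth: class-conditional fdAUG frames, context strata, ortholog
  conservation probability, and a leaky-scanning footprint model in which
  P(initiate) = min(1, TIE/TIE_ref) and the fdAUG flux is
  (1 − P_init(sAUG)) · P_init(fdAUG).

## Worked example

Simulate a 300-gene catalog with footprint tracks, annotate it, and run the
cohort, conservation, and metagene stages:

```bash
cat > sim.yaml <<EOF
n_genes: 300
seed: 7
depth: 2.0
EOF
kozakscan simulate --config sim.yaml --out-dir demo
kozakscan annotate --fasta demo/transcripts.fasta --cds demo/cds.tsv \
    --tie-table demo/tie_table.tsv --out demo/pairs.tsv
kozakscan cohorts --pairs demo/pairs.tsv --fraction 0.1 --out-prefix demo/fig1
kozakscan tiess --panels demo/panels.tsv --tie-table demo/tie_table.tsv \
    --pairs demo/pairs.tsv --out-prefix demo/tiess
kozakscan metagene --fasta demo/transcripts.fasta --cds demo/cds.tsv \
    --pairs demo/pairs.tsv --tracks demo/tracks_elongating.tsv \
    --anchor fdaug --out-prefix demo/fig2a
kozakscan report --in-dir demo --out demo/report.json
```

The report aggregates per-stage JSON summaries. For this run the weak
cohort (30 transcripts) has fdAUG frame proportions (0.367, 0.500, 0.133)
against (0.267, 0.567, 0.167) in the strong cohort — at 30 transcripts per
cohort the frame-0 contrast is not significant (chi² = 0.69, p = 0.41);
catalog-scale runs below recover it decisively. The fdAUG-anchored metagene
over the 128 transcripts passing the inclusion filters shows a pooled
downstream/upstream step change of 1.25: the footprint density downstream
of the fdAUG exceeds the density between the starts, the signature of
initiation by ribosomes that leaked past the sAUG.

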