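# glucoshift

Analysis pipeline for reciprocal glucose-shift experiments in mixotrophic
microalgae (*Chlorella sorokiniana*-style designs): identification of
**glucose-specific responsive (GSR) genes** from a four-condition RNA-seq
design, exact binomial **pathway enrichment**, LC-MS **metabolite
differential analysis**, and transcriptome–metabolome inference of the
preferred **glucose-assimilation route** (oxidative pentose phosphate vs
Embden–Meyerhof–Parnas vs Entner–Doudoroff glycolysis).

## The experimental design and the statistics

Cultures adapted to low (1.25 g/L) or high (5 g/L) glucose (**LL**, **HH**)
are shifted to the opposite medium and sampled 36 h later (**L2H**, **H2L**),
each in triplicate. Three comparisons are tested on the gene × sample count
matrix: L2H/LL, H2L/HH and HH/LL.

- **DEG calling.** Counts are scaled to equal libraries and tested with an
  exact conditional negative-binomial test (common dispersion φ estimated by
  method of moments; at φ = 0 the test reduces to the exact binomial split of
  the total). A gene is a DEG when |fold| > 4 on mean TPM (pseudocount 0.5)
  and Benjamini–Hochberg q < 0.01.
- **GSR genes.** Genes significant in *both* shift comparisons whose response
  is monotonic in glucose: up on the shift to high and down on the shift to
  low (positive correlation with glucose) or the mirror (negative). The common
  set and the monotonic fraction summarize the Venn of the three DEG sets.
- **Pathway enrichment.** For a pathway with K members in a transcriptome of
  N genes, the overlap k with a subset of n genes scores
  `fc_log2 = log2(k·N / (K·n))` and `p = P(X ≥ k)`, X ~ Binomial(n, K/N),
  summed exactly (no normal approximation).
- **Pathway consistency.** With M of N enzymes of a route regulated in the
  same direction, each enzyme is a trial with success probability 2⁻ᴹ and
  `p = P(X ≥ M)`, X ~ Binomial(N, 2⁻ᴹ). The upregulated route with the
  smallest consistency p-value below 0.05 is the preferred assimilation route.
- **Metabolome.** Ions with replicate RSD > 30% are removed, samples are
  median-normalized, differential compounds (DECs) are called by Welch tests
  on log2 intensities at fold > 4 / p < 0.01, and putative identities are
  screened at < 10 ppm mass accuracy.

A synthetic-data module generates count matrices, pathway maps and metabolite
tables with planted ground truth for all of the above, so every pipeline
stage is testable end to end.

## Worked example

`examples/pathway_enrichment_table.py` builds a 9,277-gene transcriptome with
a 237-gene subset and five pathways of known overlap, and prints:

```
pathway      K   k  log2 FC   p-value
p00910      18   8     4.12  2.97e-08
p00710      51   8     2.62  6.00e-05
p03008      83  10     2.24  6.65e-05
p00730      22   4     2.83  2.61e-03
p00220      23   4     2.77  3.06e-03
```

Each row reads: of K pathway genes, k fall in the subset — e.g. nitrogen
metabolism is 2⁴·¹² ≈ 17-fold over-represented, with a 3 × 10⁻⁸ chance of an
overlap that large arising at random.

`examples/route_preference.py` scores four candidate routes from tri-state
enzyme calls and prints:

```
OPP: 5 of 6 enzymes co-directional (up), p = 1.74e-07 [preferred]
EMP_lower: 3 of 4 enzymes co-directional (down), p = 0.00708
ED: 2 of 3 enzymes co-directional (up), p = 0.156
EMP_upper: 2 of 4 enzymes co-directional (down), p = 0.262
```

Five of six OPP enzymes moving up together is far beyond coin-flip
expectation, so OPP is marked the preferred glucose-oxidation route.

The other examples (`simulate_and_identify_gsr.py`, `metabolome_workflow.py`)
run the GSR and metabolite pipelines on synthetic data with planted truth and
print recovery numbers.

## Command line

A thin CLI wraps the library:

```sh
glucoshift simulate --seed 5 out/sim            # synthetic study + truth tables
glucoshift run-all --counts out/sim/counts.tsv --sample-meta out/sim/sample_meta.tsv \
    --annotation out/sim/annotation.tsv --pathways out/sim/pathways.gmt out/run
glucoshift report out/run
```

`run-all` executes deg → gsr → enrichment → metabolome → integration, writing
TSV tables (with full-precision JSON sidecars), a human-readable route report
and a manifest with per-stage record counts. Subcommands `deg`, `gsr`,
`enrich`, `metabolome` and `integrate` run single stages.

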