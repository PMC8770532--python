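# Methods

## Design model

Four culture conditions are modelled: adapted to low (1.25 g/L) or high
(5 g/L) glucose (LL, HH) and sampled 36 h after a reciprocal medium shift
(L2H, H2L), three biological replicates each. Every condition carries a
*target* glucose level — the level the transcriptome is responding to at
sampling time: high for HH and L2H, low for LL and H2L. The condition label
fully determines medium level, shift status and target level; these mappings
are hard-coded.

## Differential expression

**Normalization.** TPM per sample: `TPM_g = 1e6 · (c_g/L_g) / Σ_j (c_j/L_j)`.
Effective lengths default to 1,000 nt when unknown, making TPM proportional
to counts; columns sum to 10⁶ whenever any count is positive. For testing,
counts are scaled by total-count size factors (library size / mean library
size); no TMM/RLE, no GLM designs.

**Dispersion.** A single common NB dispersion φ (variance = μ + φμ²) by
method of moments: per gene and condition, φ_g = max(0, (s² − m̄)/m̄²) on
library-scaled replicate counts; φ is the median over (gene, condition)
cells with m̄ ≥ 5. Low-mean cells are excluded because their moment
estimates are dominated by Poisson noise. Moment estimators on 3 replicates
are noisy per gene but the median over thousands of genes is stable
(recovers φ = 0.1 as ≈ 0.06–0.12 in simulation; slight downward bias is the
price of the max(0, ·) truncation and is acceptable for a test that is
conservative in φ). A single replicate raises an error instructing the
caller to supply φ explicitly.

**Exact test.** After scaling, replicate counts are summed per group and
rounded. Conditional on the grand total t, the group-A total follows the
NB-convolution conditional law with weights
`w(x) ∝ Γ(x + n_A/φ)/x! · Γ(t − x + n_B/φ)/(t − x)!`
(a beta-binomial); at φ = 0 this degenerates to Binomial(t, n_A/(n_A+n_B)).
The two-sided p-value sums the probabilities of all splits no more probable
than the observed one. Ties are included with a 1e-9 relative guard on the
log scale: exactly-equal rational masses (e.g. mirrored outcomes, or
coincidences at unequal group sizes) must land on the same side of the
comparison despite floating-point rounding. Computation is vectorized in
log space (gammaln/logsumexp); per-gene cost is linear in the gene's total
count, and identical (a, b) totals are cached.

**Calls.** log2FC = log2((mean TPM_B + c)/(mean TPM_A + c)) with pseudocount
c = 0.5 (TPM units ≈ one count at the default library size); the sign is
oriented so positive means higher in the condition named first in "B vs A"
reports (the higher-glucose target state in all three design comparisons).
Grades: *significant* when |fold| > 4 and BH q < 0.01; *moderate* when
|fold| > 1.2; else unchanged. Whether the study's 4-fold cutoff applies to
TPM or count ratios is not documented; this package applies it to the
mean-TPM ratio with pseudocount, and both the folds and the pseudocount are
configurable.

**Summative (isoform-group) calls.** Enzymes with several isoforms are
additionally tested as a unit: member counts are summed per sample before
testing and member TPMs before the ratio, at the looser thresholds fold > 2
with raw p < 0.05 (no FDR — the group count is small and fixed by the
pathway). Per-isoform significance at the same thresholds feeds a
*discordance* flag: set when the summative direction opposes the majority
direction of the individually significant isoforms, the situation where a
single abundant isoform drags the sum against its siblings.

## GSR classification

GSR candidates are genes significant in both shift comparisons. A candidate
is *positive_gsr* when log2FC(L2H/LL) > 0 and log2FC(H2L/HH) < 0,
*negative_gsr* in the mirror case, otherwise *non_monotonic* (a transient
shift response). A candidate also significant in HH/LL must agree in sign
with its L2H response, else it is demoted to non_monotonic — this encodes
"consistent with the steady-state contrast" without inventing magnitude
thresholds, which is the design choice taken where the monotonicity rule
was genuinely open. Ranking of top genes uses |log2FC(HH/LL)| (the
steady-state extremes), ties broken by gene id.

## Enrichment and consistency statistics

`binomial_upper_tail(k, n, p)` sums exact terms `C(n,j) p^j (1−p)^{n−j}`
with big-integer binomial coefficients, ascending j from k with an early
stop once terms fall below 1e-18 of the running sum; a log-space (lgamma)
fallback covers the deep-underflow regime. Relative error is a few ulps per
term (verified against exact rational enumeration to 1e-14 for n ≤ 30).

*Enrichment*: trials n = subset size, success probability K/N, upper tail
P(X ≥ k), fold `log2(k·N/(K·n))`. This trial convention is fixed because it
is the one that reproduces the published table it mirrors. Zero-overlap
pathways report p = 1 with undefined (NaN) fold. A BH-adjusted column is
emitted for convenience but no thresholding uses it.

*Consistency*: with M of N route enzymes co-directional, p = P(X ≥ M) for
X ~ Binomial(N, 2⁻ᴹ). The upper tail is used uniformly; for (N=8, M=6) it
gives 3.97e-10 where the point probability gives 3.95e-10 — the package
standardizes on the tail and tolerates ~2% on that one published value, and
makes no attempt to match a published 1.5e-14 for (N=8, M=7) that the exact
tail puts at 1.41e-14.

## Metabolome

The pipeline starts at an aligned peak table (raw spectra, adduct handling
and database retrieval are out of scope). RSD = 100·sd/mean is computed
within each biological condition and the worst condition decides removal at
RSD > 30%; an all-sample RSD would count genuine between-condition signal as
technical noise and remove every true differential compound. A dedicated
QC-injection column set can be supplied instead (`qc_samples`), matching
instruments that interleave pooled QC runs. Injection-order LOESS signal
correction is replaced by per-sample median scaling to the grand median —
the correction schedule a LOESS needs (QC order, span) is not part of the
data model; the stand-in is pluggable. DECs: Welch t on log2 intensities
(the two-sample test left unspecified upstream), fold > 4, p < 0.01. Mass
matching: strict `1e6·|obs − theo|/theo < 10` ppm. A sample-level PCA on
log2 intensities is provided as a QC report only.

## Route integration

Five hard-coded graphs carry the catalogued EC numbers: EMP-upper
{5.3.1.9, 3.1.3.11, 4.1.2.13, 5.3.1.1}, ED {2.7.1.12, 1.1.1.49, 3.1.1.31}
plus three ECs absent from the transcriptome {1.1.5.2, 4.1.2.14, 4.2.1.12},
OPP {1.1.1.44, 5.1.3.1, 5.3.1.6, 2.2.1.1, 2.2.1.2, 2.7.1.15}, EMP-lower
{1.2.1.12, 2.7.2.3, 4.2.1.11, 2.7.1.40} and starch biosynthesis (including
GBSS, 2.4.1.242). Absent enzymes stay in the graph with grade *missing* and
are excluded from N. Enzyme grades come from summative EC-level records;
"same direction" counts significant *and* moderate grades, because a
moderate co-directional change still carries route information. Metabolite
calls use the DEC thresholds for significant and the 1.2-fold grade for
moderate, and are reported as supporting/conflicting relative to the enzyme
majority direction — they never enter the p-value. The preferred route is
the upregulated one with the smallest consistency p below 0.05; ties break
on larger M, then name. Per-pathway direction consistency of GSR genes uses
the GSR classification sign (equivalently the HH-vs-LL orientation).

## Synthetic data

The transcriptome generator draws baseline relative expression log-normal
(sdlog 1.2, normalized to sum 1), giving a median count ≈ 100 at the default
2 × 10⁶ library size — a realistic bulk RNA-seq dynamic range. Library sizes
vary with CV 0.1; counts are NB with φ = 0.1. Planted classes:

| class | fraction | behaviour |
|---|---|---|
| positive_gsr / negative_gsr | 0.015 each | mean × 2^(±e) wherever the target level is high (HH, L2H) |
| shift_only | 0.006 | mean × 2^(±e) in both shifted conditions (L2H, H2L) — lands in the common set but is non-monotonic |
| l2h_only / h2l_only | 0.058 / 0.043 | respond in one shifted condition only — pad the per-comparison DEG fractions to study-like levels (~9.4% / ~7.9%) without entering the common set |
| null | remainder | no effect |

Effect magnitudes are |N(3, 0.5)| truncated below 2.0 log2 units so every
planted gene exceeds the 4-fold DEG cutoff in truth; shift-responder signs
are random. Planted class *counts* are deterministic (rounded fractions);
placement and magnitudes depend only on the seed, and identical seeds give
byte-identical output.

The pathway generator fills each enriched-pathway member slot from a
GSR-class gene with probability min(1, enrich_factor × GSR fraction)
(defaults: 30 pathways of 15–90 genes, 3 enriched at factor 16), so the
expected GSR overlap has the closed form size × min(1, factor × fraction)
used by the Monte-Carlo tests. The metabolome generator plants exactly
round(frac_dec × n) differential compounds (default 18% of 409) at ±3 log2
units under multiplicative log-normal noise with sdlog 0.2 — ≈ 20%
replicate CV, the level consistent with a table whose ions survived a 30%
RSD QC filter — with m/z uniform on the 50–1,200 Da instrument window.

**What the generator does not emulate:** GC/length biases, correlated gene
modules, batch effects, isoform structure (isoform groups must be supplied
via annotations), drifting injection order in the metabolome, adducts and
isotopes. Passing recovery tests therefore demonstrate the statistics under
the stated noise model, not robustness to those artefacts.

## Numerical and degenerate-input choices

Tie handling in the exact test is inclusive (≤ observed probability) with a
1e-9 relative log-guard; all-zero totals give p = 1; all-zero samples are a
TPM error naming the sample; zero-mean metabolite ions are removed with an
explicit reason; empty route graphs yield p = 1 verdicts with a warning
rather than an error. Result tables are written as TSV with ≥ 6 significant
digits plus a JSON sidecar with full precision, so numeric round-trips
never depend on TSV rounding. All randomness flows from a single integer
seed through numpy Generators.

## Known limitations

- A single common dispersion across genes; no tagwise/trended shrinkage.
  Genes with atypically high dispersion are anti-conservative.
- The GSR recall of the double-filter design (|fold| > 4 in both shift
  comparisons) is bounded by the fold-estimate noise floor
  ≈ sqrt(2φ/n_rep)/ln 2 ≈ 0.37 log2 at φ = 0.1 with triplicates: planted
  effects between 2 and ~2.7 log2 units are recovered with materially less
  than full probability, putting overall recall of the default effect
  distribution near 85% with direction accuracy ≈ 100% and essentially zero
  false GSR calls. Recall beyond ~91% is unreachable at these noise levels
  even with error-free abundance estimates.
- The consistency test's 2⁻ᴹ success probability is a modelling convention,
  not a calibrated null; its p-values are comparative scores across routes.
- Median scaling corrects global intensity drift only; structured
  injection-order effects require a real QC-RLSC implementation.
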