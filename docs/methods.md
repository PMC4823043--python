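# Methods

`ripchip` implements the computational half of an Ago2-RIP-Chip experiment:
identifying the transcripts a miRNA loads into the RNA-induced silencing
complex (RISC), by comparing Argonaute-2 immunoprecipitated RNA (IP) against
total RNA (T) on two-color expression arrays. Every analysis stage is paired
with a synthetic-data generator that plants a known ground truth, so the
whole pipeline can be exercised and scored without any array download.

## Array preprocessing (`ripchip.arrays`)

Signals are linear-scale fluorescence values, one column per sample channel.
The expected design is two dye channels (Cy3/Cy5 technical replicates of the
same hybridization) per (cell line, construct, fraction) sample, with
fractions `T` and `IP`.

**Quantile normalization** is applied jointly across all channels: each
column's sorted values are replaced by the cross-column mean of order
statistics, and tied input values receive the mean of the normalized values
of the tied ranks. This makes every channel share one distribution (the
operation is idempotent and rank-preserving per column). Normalization is
applied before filtering; the two steps commute only approximately, and
normalize-then-filter matches a single-session analysis of all arrays.

**Detection.** When a table carries no detection flags, a probe is called
detected in a channel iff its signal strictly exceeds the channel's 10th
percentile (configurable). The strict inequality means a constant channel
detects nothing; pre-existing flags are never overwritten.

**Probe QC** removes, in fixed order:

1. probes detected in fewer than half of the sample channels
   (`min_detected_fraction = 0.5`; a probe detected in exactly half is
   retained — the literal reading of "not detected in more than half"), then
2. probes whose Cy3/Cy5 signals disagree by more than `max_dye_fold = 2`
   in any dye pair, computed as `max(a,b)/min(a,b)` after flooring both
   signals at 1.0 fluorescence unit so zero-level signals cannot produce
   unbounded ratios.

Dye channels are then averaged arithmetically on the linear scale (the IP/T
ratio downstream is a ratio of averaged linear signals).

## Targetome calling (`ripchip.targetome`)

The IP/T ratio per probe and sample uses a denominator floor of 1.0 linear
unit. Membership in the targetome is `IP/T >= 2` (inclusive). A probe is a
*miRNA-specific* target between a test and a reference construct when

    ratio_test >= 2   and   ratio_test / ratio_ref >= 2,

both thresholds configurable. By default a probe must be present (retained)
in both constructs; a flag admits reference-absent probes on the test
criterion alone. Sponge-inhibition designs reuse the same rule with roles
swapped (test = control construct, reference = sponge construct).

Gene-level calls collapse probes by the maximum ratio per gene (the
representative probe is recorded); unannotated probes are counted and
reported, never silently dropped. Cross-sample categories partition the
ratio axis into half-open bins — NotExpressed (no retained probe),
Enriched `[2, inf)`, MildlyEnriched `[1.5, 2)`, NotEnriched `(0, 1.5)` —
resolving the overlap of the conventional "1.5 <= IP/T <= 2" and
"IP/T >= 2" descriptions in favor of mutual exclusivity.

## Seed-site scanning (`ripchip.seeds`)

From a mature miRNA (5'→3', length >= 8) the canonical seed-match sites on
the target strand are: 6mer = reverse complement of positions 2–7,
7mer-m8 = reverse complement of 2–8, 7mer-A1 = 6mer + A, 8mer = 7mer-m8 + A
(all DNA alphabet). For hsa-miR-155-5p these are GCATTA and AGCATTAA for the
6mer and 8mer.

Scanning is single-strand only (miRNA sites live on the transcript),
case-insensitive, U≡T, with overlapping occurrences counted and 1-based
positions reported. Counting is *inclusive* by default: a genomic 8mer also
counts as a 6mer, consistent with published site-content tallies in which
6mer carriers are a superset of 8mer carriers; an exclusive mode subtracts
occurrences contained in a longer catalog site. Ambiguity codes never
match. CDS sequences go through the identical scanner; the host feature is
metadata.

Overlap with an external prediction list (e.g. TargetScan) is tested with a
Pearson chi-square on the 2×2 membership table, one degree of freedom, no
continuity correction by default (Yates by flag); zero margins are an
error.

## Gene-set enrichment (`ripchip.gsea`)

Genes are ranked by log2 of the collapsed IP/T ratio, descending, ties
broken by gene id. The enrichment score is the weighted Kolmogorov–Smirnov
running sum (weight exponent p = 1 by default, p = 0 available): hits add
`|metric|^p / Σ_hits |metric|^p`, misses subtract `1/(N − N_hits)`, and ES
is the signed maximum deviation from zero.

The null is a *gene-label permutation*: random same-size gene sets drawn
from the ranked universe, shared per set-size stratum. With one IP/T pair
per fraction there are no sample labels to permute, so a preranked
gene-permutation variant is the only implementable null; this is a
deliberate, documented difference from phenotype-permutation GSEA.
NES divides ES by the mean |null ES| of matching sign. The permutation
p-value is sign-stratified with add-one smoothing — for positive ES,
`p = (1 + #{positive null >= ES}) / (1 + #positive null)`, mirrored for
negative — which keeps null p-values approximately uniform and never
exactly zero. Motif gene sets are identified by an explicit flag (synthetic
collections) or a name regex (CLI); the motif-set summary reports the
fraction of the top-k sets flagged as motif sets and the rank of any named
set.

## Growth-assay statistics (`ripchip.growth`)

GFP competition series are normalized per replicate by the first measured
day (relative value 1 there, by definition), and the model is fit to
`response = relative value − 1`. The fixed effects are construct × day
interaction terms only — no intercept and no main effects, because the
response is identically zero at baseline. Baseline rows are kept in the
design (all-zero rows) but excluded from the fitting likelihood: they are
zero by construction, so they carry no error information, and treating
their zero residuals as data measurably deflates variance estimates.

Day is categorical by default; a linear coding (one slope per construct in
`day − baseline_day`) is available and is the natural scale for estimating
a per-day growth advantage.

**Inference.** For balanced categorical designs (complete replicate × day
grid) the joint construct × day Wald contrast is evaluated by its exact
decomposition: under the random-intercept model the contrast splits into a
between-replicate comparison of replicate means (F with 1 and g−2 df,
g = total replicates) and the classical split-plot interaction test on
within-replicate deviations (F with d−1 and (g−2)(d−1) df, d = post-baseline
days). The two statistics are independent and exactly F-distributed under
the model, and their p-values are combined by Fisher's method — giving an
exact level-α joint test at any replicate number. This replaces the naive
REML Wald chi-square, which is markedly anti-conservative at the 3
replicates/arm typical of these assays (empirical type-I error 0.09–0.16 in
simulation, versus 0.054 for the exact route at α = 0.05, 500 null
simulations). Unbalanced or linear-coded designs fall back to a REML
random-intercept fit (statsmodels `MixedLM`) with the Wald statistic
referred to F(q, n − p − g) (containment-style df), and to ordinary least
squares with a warning when the random-intercept variance estimate
collapses to zero.

The Mann–Whitney U test uses the exact null distribution when
`n_a + n_b <= 16` with no ties, otherwise the normal approximation with tie
and continuity corrections; two identical groups return `U = n_a·n_b/2`,
p = 1 rather than an error.

## Synthetic data (`ripchip.simulate`)

The generator emulates the paired RIP-Chip design: per construct, T and IP
fractions, each with Cy3 and Cy5 channels. Probe baseline log2-intensities
are Normal(10, 1.5) — reproducing lognormal array dynamic range without
modeling scanner physics. Planted target genes receive a log2 IP
enrichment; `construct_attenuation` scales that enrichment per construct
(0 for an empty-vector control, 1 for full miRNA activity, values just
below the control for a weak sponge). Dye effects and signal noise are
independent Normal draws per probe and channel on the log2 scale; detection
dropout sets a boolean flag (it does not zero the signal), keeping QC
separable from intensity modeling. UTRs are uniform-ACGT strings of fixed
length with one 8mer seed site inserted at a planted-rate-dependent subset
of genes; insertion guarantees exactly one occurrence (re-draw on
collision). The growth generator produces relative values
`1 + advantage·(day − day0) + replicate shift + residual` converted to GFP
percentages and clipped to (0, 100), with the baseline day exactly 1.

Default conditions follow the scale of the real experiment: 8000 genes
(order of the consistently expressed fraction of a 44k array), 54 planted
targets, per-target folds drawn from [2.0, 12.6], log2 noise sd 0.25, dye
effect sd 0.05, 2% dropout; competition assays run 3 replicates/arm on a
~twice-weekly three-week schedule (days 4–22) with replicate and residual
sd 0.05. Noise magnitudes are plausibility choices — per-probe variances
and detection rates of the original arrays are not published — and are
deliberately not tuned. Presets: `paper-like`, `zero-noise`, `null`, and
`sponge-weak` (attenuation 0.8, i.e. a sponge that removes only 20% of
target loading).

What the generator does *not* model: cross-hybridization, spatial array
artifacts, probe-affinity sequence effects, GC composition of UTRs, or
correlated noise between fractions. Passing tests therefore demonstrate the
correctness of the analysis logic under a faithful-but-idealized noise
model, not performance on real arrays.

## Numerical and design choices

- Seeds: a single pipeline seed is fanned out to per-stage child seeds via
  `numpy.random.SeedSequence([seed, stage_index])`, so stages can be rerun
  in isolation; all generators accept explicit seeds and are bit-reproducible.
- Floors: 1.0 linear unit on T signals (ratio denominator) and on dye-ratio
  operands.
- Tie-breaks: ranking ties by gene id; NES ranking ties by ES then set
  name; quantile-normalization ties by rank-mean.
- Degenerate inputs: constant detection channels detect nothing; identical
  Mann–Whitney groups return p = 1; noiseless growth data yield p = 0 or 1
  by direct comparison instead of 0/0.
- With exactly 8000 genes and 54 targets at folds down to 2.0, specific-gene
  recall sits near (and occasionally at) 0.9 — targets planted at the
  calling threshold are genuinely borderline under noise. This is a
  property of the condition, not a bug.

## Known limitations

- The mixed-model exact route requires a complete replicate × day grid; with
  dropout-ridden series inference reverts to the asymptotic Wald F, which
  is less well calibrated at very small replicate numbers.
- Benjamini–Hochberg on permutation p-values is provided as a convenience
  only; no further FDR machinery or leading-edge analysis.
- The scanner matches exact seed strings; no thermodynamic or context
  scoring, no conservation.
- Real Agilent feature-extraction exports must be reduced to plain
  tab-separated signal/flag tables before import; binary formats are out of
  scope.
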