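# Methods

`methfid` re-implements, as a tested pipeline on synthetic data with
known ground truth, an analysis of transgenerational CpG-island (CGI)
methylation fidelity: differential-methylation calling on two-color
CGI array data across cell generations, classification of probes into
five methylation-propagation categories, transcription-factor
binding-site (TFBS) enrichment of each category against GC/length-
matched backgrounds, and a stochastic maintenance/de-novo methylation
simulator. This note records the models, the parameters that matter,
and the design choices made where the design was genuinely open.

## Generative model of the synthetic study

Each synthetic probe is a 60-mer promoter oligo with a per-timepoint
true methylation level in [0, 1] for (parental, g1, g3, g5). A probe's
log2 net fluorescence on the channel carrying sample *s* is

    x_s = baseline + c * level_s (+ noise),

with a per-probe log-normal baseline (probe efficiency;
`baseline_log2_mean = 9`, `baseline_log2_sd = 0.25` log2 units) and a
dynamic range `c = intensity_range_log2 = 8` log2 units across the
0–1 methylation scale. The progeny-over-parental log-ratio is therefore
`M_true = c * (level_t − level_parental)`. Noise has three components:

* **inter-sample** (`bio_sd = 0.1` on M): hybridization-to-
  hybridization biological/technical variation — the quantity the
  empirical-Bayes null variance τ₀² estimates;
* **intra-sample pixel noise** (`pixel_sd_scale = 0.08`,
  `n_pixels = 25`): per-spot pixel SD columns are written so that
  SD/√n_pixels is exactly the standard error used to perturb the
  reported channel means, closing the loop on the delta-method
  variance;
* **intensity-dependent dye bias**: a smooth sinusoid b(A) of
  amplitude `dye_bias_amplitude = 0.3` added to the red/green
  log-ratio, so it enters swap arrays with opposite sign and cancels
  in a dye-swap average.

With all three set to zero the true log-ratio is recovered exactly —
a property the tests assert.

**Trajectories.** Direction patterns follow the five-category pattern
table: stochastic hyper/hypo probes sample one of their three listed
patterns, random probes one of the ten listed mixed patterns; an "up"
is a level step of `effect_size / c` (`effect_size = 1.0` log2 units;
the g5 step is 1.5×). Parental starting bands are
hyper U(0.10, 0.45), hypo U(0.55, 0.90) (hyper starts low, hypo high —
the shared-starting-level structure the overlap analysis expects),
heritable-high U(0.92, 0.98), heritable-low U(0.02, 0.08), random
U(0.35, 0.65), and an uncategorized null pool U(0.16, 0.84) with
`uncategorized_multiplier = 4` probes per planted-category count.

Two of these choices are load-bearing and deliberate:

1. **Nulls dominate at every intensity.** Loess normalization assumes
   the local majority of probes at any intensity is non-differential
   (true of the real study, where at most ~6% of probes are
   differential). Narrow, disjoint hyper/hypo bands make differential
   probes the local majority in their intensity range and loess then
   absorbs genuine signal. The wide bands plus the broad null pool
   keep the differential fraction small everywhere.
2. **Modest probe-efficiency spread.** The heritable categories are
   defined on absolute fluorescence (>85% / <15% of the array
   maximum), which presumes fluorescence ranks methylation. With the
   percentile scaling described below, planted levels of 0.92–0.98
   map to relative levels ≈0.87–0.97, so a large probe-efficiency
   spread would straddle the 0.85 floor for reasons unrelated to
   methylation. `baseline_log2_sd = 0.25` keeps the rule meaningful;
   real arrays would need probe-effect correction, which is out of
   scope and a known limitation.

**What the generator does not emulate:** restriction-fragment logic
(the methylation-sensitive digestion that methylation arrays assay),
PCR amplification bias, scanner saturation, spatial (print-tip)
artifacts, and probe-specific affinity differences beyond the
log-normal baseline. Passing tests therefore demonstrate the
*analysis* is correct under a faithful noise model, not that it would
be robust to every artifact of scanned slides.

**Motif planting.** The synthetic motif library holds informative
10–12 bp matrices (one dominant base per position, 12:1 counts) —
typical vertebrate TF motif widths; shorter consensi occur too often
by chance in GC-rich 60-mers to be distinguishable from background at
the default score cutoffs. The library splits in half: group X is
planted (rate `motif_plant_rate = 0.3`, per-position argmax consensus,
either strand, random offset) in stochastic-hypo + heritable-high
probes, group Y in stochastic-hyper + heritable-low, mirroring the
shared-starting-level overlap structure; random and uncategorized
probes receive none.

## Normalization

Background-subtracted net intensities give M = log2(net_p/net_par) and
A = ½·log2(net_p·net_par); nonpositive nets are flagged `low_signal`
and carried through untouched (flagging is auditable; imputation is
not). The intra-spot variance of M uses the first-order delta method
with channel standard errors SD/√n_pixels:

    s²_intra = (1/ln 2)² Σ_channels (f_sd² + b_sd²)/(n_pixels · net²).

Loess is a locally weighted degree-1 regression of M on A (tricube
weights, 3 robustifying iterations, global — not print-tip-wise — as
the span of a 60-mer promoter array design gives no tip structure to
exploit). The default span is 0.3, the conventional value for MA-plot
loess (limma's default); at 0.4 a full-period smooth bias leaves
per-decile residuals above 0.05. Loess is not exactly idempotent —
a second pass moves corrected log-ratios by a few times 10⁻² on
smooth-bias input (the smoothing bias of the residual) and is tested
as a contraction, not a fixed point.

Dye-swap merging averages M after orienting both replicates
progeny-over-parental (so the merged variance is (s²_a + s²_b)/4), and
the QC report gives Pearson correlations of log2 net intensities of
the channels carrying the same biological sample in the swap/non-swap
pair, before and after normalization — the reproducibility check that
motivates trusting single arrays for g1 and g5.

## Empirical-Bayes differential calling

Per generation comparison, the normalized log-ratios follow a
two-component zero-centered normal scale mixture

    M_p ~ (1−π₁) N(0, τ₀² + s²_p) + π₁ N(0, τ₁² + s²_p),

with the probe's intra-sample variance s²_p known from pixel
statistics and the shared τ² capturing inter-sample variation. The
original study's exact likelihood is unpublished; this surrogate keeps
its stated structure (normal components, intra- plus inter-sample
variance decomposition) and its decision rule — the posterior
probability of the wide component, thresholded at 0.80, with direction
from the sign of M. The posterior depends on |M| only, so calls flip
up↔down under negation. Whether the original differential component
had a nonzero mean is unknowable from the source; the surrogate is
symmetric.

EM details: deterministic initialization π₁ = 0.05,
τ₀² = 0.25·var(M), τ₁² = 4·var(M); the τ² M-steps are 1-D bounded
searches on log τ² accepted only when they improve the expected
complete-data log-likelihood (generalized EM, so the log-likelihood
trace is nondecreasing); convergence when the gain drops below 1e-6.
Two devices make the fit identifiable and well-behaved:

* a minimum scale separation τ₁² ≥ 4·τ₀². Without it, on null data the
  two components collapse to equal variances and the likelihood is
  flat in π₁; with it, π₁ → 0 when no wide component exists.
* a joint rescaling step (c·τ₀², c·τ₁²) each iteration, because the
  coordinate updates can deadlock on the separation boundary with both
  variances too small.

Probes with M exactly 0 are called even regardless of posterior
(tie rule); low-signal probes are even with a missing posterior.

## Category classification

The 27 possible (g1, g3, g5) direction triples map deterministically:
3 patterns to stochastic hypo, 3 mirrored to hyper, 10 listed mixed
patterns to random; (even, even, even) splits on levels into heritable
high (all four relative levels > 0.85, spread ≤ 0.15), heritable low
(all < 0.15, spread ≤ 0.15) or uncategorized. The 10 unlisted mixed
patterns (e.g. down, down, even) default to uncategorized — consistent
with the uncategorized pool serving as background set #2 — with a
switch to merge them into random, since the source table is silent.

"Maximal microarray fluorescence" is operationalized robustly as the
99.5th percentile of both channels' log2 net intensities pooled per
array (the 0.5th percentile as the floor), resisting single-spot
saturation; a probe's relative level is the clipped affine rescaling
of its channel intensity between those percentiles, with the parental
level averaged over its three arrays.

Cluster analysis chains same-gene probes whose midpoints (0-based
half-open coordinates) lie within 1500 bp by single linkage — the
distance below which most CGIs fit — and a cluster is *consistent*
when all members share one category; the summary reports, per
category, the consistent fraction of multi-probe clusters containing
that category.

## Stochastic maintenance / de-novo model

A site-level Markov model: per division each methylated site stays
methylated with maintenance probability μ, each unmethylated site
converts with de-novo probability δ, independently across sites and
cells. The population mean follows p_{t+1} = δ + p_t(μ − δ), which for
μ > δ contracts geometrically (ratio μ − δ) to p* = δ/(δ + 1 − μ);
generations to come within ε of p* from p₀ are
⌈ln(ε/|p₀ − p*|)/ln(μ − δ)⌉. With symmetric rates δ = 1 − μ = 0.02 the
equilibrium is exactly ½, and a population seeded from equal fully-
methylated and fully-unmethylated clones stays at 50% in expectation —
the default simulation (1000 cells × 100 sites, 30 generations)
verifies both the steady state and the ~30-generation convergence
scale (e.g. μ = 0.935, δ = 0.065 from p₀ = 0 reaches 1% of equilibrium
in ⌈28.09⌉ = 29 generations). A strand-aware hemimethylation model is
a documented extension point, not implemented: the source describes
the process only at the level of maintenance and de-novo efficiencies,
and μ is a free parameter rather than a fitted quantity.

## TFBS scanning and enrichment

Weight matrices come from a TRANSFAC flat-file dialect (ID/NA lines,
numbered count rows, `//` terminator); counts gain a pseudocount of
0.25 per cell before frequency conversion so minimum frequencies are
strictly positive. Scoring is MATCH-style: position information
I(i) = Σ_b f(i,b)·ln(4f(i,b)), window score Σ_i I(i)·f(i, b_i), and
the matrix similarity score (MSS) min–max normalizes between the
per-position minimum and maximum frequencies; the core similarity
score (CSS) applies the same formula over the 5-position window of
maximal summed information. N bases contribute the position minimum; a
zero-information matrix scores 1 by definition. Both strands are
scanned with offsets reported in input-sequence coordinates. Default
cutoffs css ≥ 0.75, mss ≥ 0.85 (the original cut-off profile is not
recorded; these sit in MATCH's conventional range and are
configurable).

Enrichment uses presence/absence per sequence (≥1 hit) as the 2×2
unit — "hit frequency per probe" is ambiguous between presence and
hit counts, and presence gives a clean sequence-level sampling unit; a
per-hit-count mode exists behind a flag. One-sided (greater) Fisher
exact tests are thresholded at α/(n_matrices·n_categories) — with a
459-motif library and 5 categories, 0.05/459/5 = 2.2×10⁻⁵; the divisor
always uses the number of matrices actually scanned. Two background
sets: (1) random sequences matched per categorized probe for exact
length and expected GC (G and C each at g/2); (2) uncategorized probe
sequences of identical length with GC within ±0.05 (nearest-GC
fallback), sampled without replacement while the pool lasts, with
replacement afterwards and a count of replacements in the report.
Category-pair overlaps of significantly enriched motif sets are
reported as a count matrix plus per-pair membership.

## Expression filter

Three independent gates on a probes × samples log2 expression matrix
with P/M/A detection calls: fraction presence (P = 1, M = 0.5, A = 0)
of at least 0.5 in at least one group; Welch's t-test on log signals
at p < 0.01; and |log2 fold change| ≥ 1.2. The fold-change cutoff is
read on the log2 scale — the source reports fold changes "(log2)"
against the same cutoff — with a linear-scale mode behind a flag.
Probes with zero variance in both groups have an undefined p, are
flagged and never pass.

## Pipeline, reproducibility, problem sizes

The pipeline chains simulate → normalize (with the g3 dye-swap merge)
→ call → classify → cluster → enrich (both backgrounds) → report; the
expression filter and the methylation-dynamics simulator consume
separate inputs and run as standalone subcommands. Every intermediate
persists as TSV/FASTA/JSON so any stage reruns in isolation; one
global seed derives all substreams, and rerunning a configuration
reproduces identical SHA-256 file digests. Default sizes — 400 probes
per planted category plus 1600 uncategorized (~3,600 probes), 12
motifs, 2 backgrounds per sequence — complete in under a minute on one
CPU; the 1000 × 100 Riggs simulation takes a few seconds. The run
report includes category counts, per-category recall against planted
truth, significant-motif counts per category and background set, the
overlap matrix, and the QC correlations.

## Known limitations

* The heritable/stochastic category boundary depends on the
  percentile-based level scaling; probes planted within ~0.03 of the
  0.85/0.15 floors can land on either side under noise.
* The EB surrogate is symmetric and two-component; it does not model
  asymmetric hyper/hypo prevalence within a generation.
* The simulator is single-strand site-level; hemimethylation dynamics
  and strand asymmetry of maintenance are not represented.
* Real-data category counts and enriched-TF lists from the original
  study depend on its deposited arrays and unpublished model internals
  and are not reproduction targets here.
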