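# Methods

## Measurement model and study design

The pipeline targets single-channel oligonucleotide arrays hybridized
with RNA from a fungus growing alone (`Tv`) or in co-culture with maize
(`M+Tv`) or tomato (`T+Tv`) roots.  Co-culture extracts contain plant
RNA in varying proportion, so the amount of fungal RNA on each array
differs by an unknown per-array factor.  The working measurement model
is multiplicative on the linear scale and additive in log10:

    log10 signal(g, s) = baseline_g + effect_{g, c(s)} + gain_s + ε,
    ε ~ Normal(0, sd(μ)),

where `gain_s` is the per-array loading/labelling factor and the noise
standard deviation `sd(μ)` decreases with noise-free intensity μ
(replicate scatter on arrays is largest near the detection floor).
Spike-in control probes follow the same model with their known log10
relative concentration in place of `baseline + effect`; they are blind
to condition, which is exactly what makes them usable for calibration.

## Normalization

Three monotone per-sample maps, composed in order; input and output are
linear-scale.

1. **Anchoring.**  Each array's log10 signals are shifted additively so
   the anchor spike-in (`E1A_r60_a20`) reads 3.83, its own log10
   relative concentration.  The target value choice makes the anchor a
   fixed point of the concentration mapping in stage 2; any other common
   target would differ only by a global constant.
2. **Spike-curve interpolation.**  Per array, replicate probes of each
   spike are averaged (arithmetic mean of log10 signals), giving up to
   ten (log10 signal, log10 concentration) knots sorted by
   concentration.  Non-monotone signal sequences — possible at the dim
   end of the panel — are repaired by pool-adjacent-violators on the
   signal coordinate; exactly tied repaired knots are separated by
   1e-9 so the piecewise-linear map stays invertible.  Probes outside
   the knot range are mapped by linear extension of the terminal
   segments (the extrapolated fraction is reported as a diagnostic;
   about 1–3% per array at the default design).
3. **Percentile scaling.**  Each array is divided by the 75th-percentile
   intensity of its non-control probes (linear-interpolation quantile),
   then the whole matrix is multiplied by the geometric mean of those
   quantiles.  Controls are excluded because spikes are not expression
   signal; the geometric-mean rescaling keeps values near the raw
   magnitude so the downstream baseline subtraction of 10 keeps the
   intended meaning.

Properties that follow: within-array rank order is preserved by every
stage; on noise-free data with arbitrary per-array gains the chain
removes the gains exactly (null genes become constant across arrays, a
planted 4-fold effect comes through at exactly 4.0); a second
normalization pass is the identity once the spike panel is exactly
consistent with its concentrations.  With measurement noise on the spike
probes themselves, idempotence and the anchor fixed point hold only
approximately — the spike curves are re-estimated from noisy knots.

## Regularized t-test

With 3–5 replicates per group, per-gene variances are too unstable for
an ordinary t-test.  Each group's gene variance is therefore shrunk
toward a *background variance*: genes are ranked by their group mean,
and the background for gene *i* is the arithmetic mean of the sample
variances of the `w` genes in the window centered at rank *i* (windows
are shifted, never shrunk, at the edges, so every gene's prior rests on
exactly `w` genes).  The regularized variance with prior weight ν₀ is

    σ̃² = (ν₀·σ²_bg + (n−1)·s²) / (ν₀ + n − 2),

and the statistic

    t = (x̄_A − x̄_B) / √(σ̃²_A/n_A + σ̃²_B/n_B),
    df = (n_A + ν₀ − 2) + (n_B + ν₀ − 2),

is referred to Student's t.  Defaults: w = 101, ν₀ = 8, baseline
subtraction 10.0 (values floored at 1.0 before log10), α = 0.05 with
Benjamini–Hochberg step-up correction.  Testing happens on log10 signals
because the noise model is multiplicative; fold changes are reported
from linear group means of the normalized values *before* the baseline
floor, matching how transcript-abundance ratios are conventionally
quoted.

Two numerical conventions deserve note:

- The weights of σ̃² sum to (ν₀+n−1)/(ν₀+n−2) > 1, so σ̃² is *not* a
  convex combination of s² and σ²_bg: when both agree on a value v the
  regularized variance is v·(ν₀+n−1)/(ν₀+n−2) (e.g. 10v/9 at n = 3,
  ν₀ = 8).  This inflation makes the test deliberately conservative.
- The df convention mirrors the denominators of the two posterior
  variances.  It is checked by null simulation rather than asserted:
  on full-pipeline null data the raw p < 0.05 fraction averages ≈ 0.033
  (range ≈ 0.011–0.084 over seeds).  Two effects shape this: the
  variance inflation above depresses the mean rejection rate below
  nominal, and spike-curve estimation error is shared by all genes of
  an array, correlating gene-level p-values and widening the
  seed-to-seed spread well beyond binomial.  The test errs on the
  conservative side — it does not inflate false discoveries — and the
  Benjamini–Hochberg step keeps the null FDR fraction at zero in
  practice.  Genes floored to a constant in every sample get t = 0,
  p = 1 with a warning rather than an error.

## Host-specificity calling

From the three pairwise contrasts (M+Tv vs Tv, T+Tv vs Tv, M+Tv vs
T+Tv): *up-regulated* means significant with the plant condition above
the control.  The host-specific set is

    significant(MvsT) ∩ [up(MvsC) ∪ up(TvsC)],

split into maize- and tomato-preferential by the sign of the MvsT
statistic; the reported tomato/maize ratio is derived from the same
log10 group means, so sign and ratio can never disagree.  No extra fold
cutoff is applied.  Genes up on both hosts but not host-differential
are `shared_up`; significant only between hosts, `host_regulated_only`.
The counts obey |up(M)| + |up(T)| − |shared| = |union| on every run.

## Family aggregation and clustering

Family summaries sum, per condition, each member probe's mean across
replicate arrays; member SEMs (SD/√n, SD with ddof 1) combine by
√(Σ SEM²) — exact if members were independent, an approximate
variability measure otherwise.  Control-relative expression is
log10(signal / mean control signal per gene), control columns included;
genes with zero control mean are excluded with a warning.  Clustering is
agglomerative with average linkage on Euclidean distances — the
conventional defaults of desktop expression-clustering tools, recorded
here as a convention, not a claim about any particular historical run.
scipy's deterministic linkage plus stable input ordering fixes the leaf
order; dendrograms export to Newick.

## qPCR quantification

A dilution series with calibration-slope magnitude s implies efficiency
E = 10^(1/s) per cycle (s = 3.3219 ⇒ E = 2).  The built-in validation
panel of eleven assays has slopes 3.36–4.25, i.e. efficiencies
1.72–1.99; one xylanase assay falls below the 1.8 flag threshold and is
marked below-optimal.  Abundance per sample is E_ref^Ct_ref /
E_goi^Ct_goi with technical duplicates averaged on the Ct scale before
the ratio and biological replicates summarized (mean ± SEM) after.
Per-assay efficiencies are used because the panel's slopes differ
materially; a pure ΔCt mode (all E = 2) is available as a toggle.  The
qPCR–array agreement fit is ordinary least squares of log10(array) on
log10(qPCR), reported as exponent, prefactor and R².

## Synthetic-data generator

Defaults encode the study design: 11,645 gene probes, duplicate
technical-replicate probes for 100 genes, 536 control spots of which ten
spike-ins (two replicate probes each, concentrations 0.83–5.33 in 0.5
steps, containing the 3.83 anchor), groups Tv:5 / M+Tv:3 / T+Tv:3.
Per-gene baselines are Normal(2.5, 0.7) in log10; per-array gains
uniform on ±0.3 (about a 2-fold loading range); noise SD interpolates
from 0.15 at low intensity to 0.05 at high intensity, typical replicate
scatter for single-channel arrays.  Planted effects are additive in
log10: 50 shared-up, 50 maize-specific, 50 tomato-specific and 25
opposite-direction host-differential genes, fold changes drawn
log-uniformly between 2.5 and 60 — the range of robustly root-regulated
transcripts in this system; `shared_lfc` pins the shared class to one
value (the recovery benchmarks use 4-fold).  Duplicate probes share a
gene's expectation but draw independent noise.

What the generator does *not* emulate: plant-transcript
cross-hybridization, probe-sequence effects, spatial array artifacts,
saturation, or background structure beyond a constant offset.  Passing
recovery tests therefore demonstrate correctness of the computational
chain under the stated measurement model, not performance on any real
hybridization.

## Problem sizes and determinism

Unit tests run on matrices of a few hundred to a few thousand genes;
end-to-end checks (null calibration, planted-effect recovery, the
acceptance script) use the full 11,645-gene design, which normalizes
and tests in a couple of seconds.  All stochastic steps flow from a
single integer seed through `numpy.random.default_rng`; identical seeds
give bit-identical datasets.

## Known limitations

- The regularized test's calibration is conservative, not exact (see
  above); borderline inductions near the low-intensity floor are the
  main misses in recovery benchmarks.
- Baseline flooring discards information for genes at or below the
  background constant; such genes cannot be called.
- The spike-curve extrapolation beyond the panel range is linear and
  unverified by construction; the extrapolated fraction is logged so
  users can judge exposure.
- The GEO series-matrix reader targets the generic `!`-prefixed
  tab-delimited dialect; sample conditions always come from an explicit
  design table, never from free-text titles.
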