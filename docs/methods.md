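# Methods

## Model

A single promoter initiates transcription at rate α (initiations/min).
A fraction f ∈ [0, 1) of initiating polymerases terminates within the
5′ UTR; the rest read through into the ORF. Each transcript segment
decays with a first-order constant λ (min⁻¹), so at steady state

    Int_UTR = α / λ_UTR,          Int_ORF = (1 − f)·α / λ_ORF.

After transcription arrest at t = 0 the relative abundance of a segment
follows N(t) = e^(−λt), and t½ = ln2/λ.

From these two identities everything else follows. For two measured
species the synthesis-rate ratio factors into measurable fold changes,

    FCsynt(i,j) = αᵢ/αⱼ = (Intᵢ/Intⱼ)·(λᵢ/λⱼ),

and under the single-promoter assumption FCsynt(UTR, ORF) = 1/(1 − f),
giving the termination fraction f = 1 − 1/FCsynt. A UTR/ORF synthesis
ratio below 1 carries no evidence of termination; `termination_fraction`
then returns 0 with an explicit no-evidence flag rather than a negative
fraction. Comparing the same segment across conditions instead reads
FCsynt as a transcription-rate change (its reciprocal is the factor by
which initiation dropped).

Assumptions worth keeping in mind: one promoter feeding both segments;
strictly first-order decay with no lag after the transcription block
(no drug-penetration delay term, no multi-exponential mixtures); a
reference gene that is stable on the chase timescale; amplification
efficiency exactly 2 so that one cycle equals one doubling.

## Quantification

Classic comparative-Ct: technical replicates are averaged on the Ct
scale (geometric averaging of abundances), ΔCt = Ct(target) − Ct(ref)
per RNA sample, ΔΔCt is taken against the t = 0 calibrator of each
series (condition × region × biological replicate), and
rq = 2^(−ΔΔCt). Reference wells are matched per RNA sample, so all
regions of one sample share the same reference mean. Biological series
are *not* averaged here; they pass through to the fit, which pools
them. No efficiency correction or melting-curve QC is attempted.

## Decay fitting

`fit_exponential_decay` minimises Σ(rq − N₀e^(−λt))² over λ > 0,
N₀ > 0 with all points of a compartment pooled (2 probed regions × 3
biological replicates = 6 series in the reference design). This is the
plain unweighted fit on the abundance scale. N₀ stays free even though
every series is normalised to 1 at t = 0 — it absorbs calibrator noise.
Start values come from ordinary least squares on log rq vs t; the
trust-region solver runs with gradient tolerance 1e−8 and a 500-
iteration cap. An optimum pinned at the λ ≥ 0 boundary (non-decreasing
data) is returned flagged with `half_life = inf` instead of a
meaningless rate. Non-convergence raises an error carrying the best
iterate.

### Confidence intervals

Intervals come from a nonparametric bootstrap at the series level:
whole series are resampled with replacement and the pooled fit
repeated. The interval itself is a studentised t-interval on the log
half-life scale — `est · exp(∓ t_crit · se_log)` with the bootstrap SE
of log t½ and n_series − 1 degrees of freedom. The raw percentile
interval is exposed (`method="percentile"`) but is not the default:
with only ~6 resampling units percentile intervals are systematically
too narrow (measured 81% coverage at nominal 95% under the reference
design), whereas the studentised log-scale form restores near-nominal
coverage (≥ 90% at both the fastest and slowest half-lives probed, per
the test suite's coverage simulations). The log scale respects the
right-skew of a quantity derived as ln2/λ. A resample that hits the
no-decay boundary makes the SE infinite and the interval (0, ∞) —
honest uncertainty, not an error. Default 1000 resamples; the suite's
coverage checks use 300 per outer replication, which stabilises the SE
far below the coverage tolerance at a third of the cost.

## Synthetic data

The generator emits exactly what the pipeline consumes, under the
reference study design unless overridden:

| parameter | default | meaning |
|---|---|---|
| α | 1 initiation/min | arbitrary units; only ratios matter |
| f_term | condition-specific (0.959 mock / 0.653 UV in the pipeline presets) | terminating fraction |
| λ_UTR, λ_ORF | ln2/3.1, ln2/7.2 min⁻¹ (mock); ln2/17.1, ln2/7.5 (UV) | decay constants |
| timepoints | 0, 5, 10, 30 min | chase sampling grid |
| replication | 2 regions × 3 biological × 3 technical | per compartment |
| σ_Ct | 0.15 cycles | additive Gaussian noise per well |
| ref_ct_mean | 10 cycles | abundant stable reference (16S-like) |
| baseline_offset | 12 cycles | sets target Ct scale vs reference |
| uv_alpha_factor | 2.52·3.1/17.1 ≈ 0.457 | initiation reduction under UV implied by the measured intensity and stability changes |

Noise is additive Gaussian on the Ct scale (log-normal on abundance),
which matches how qPCR error behaves; σ = 0.15 cycles per well is a
typical technical spread for SYBR assays. The reference gene is
simulated decay-free — 16S rRNA is effectively stable over a 30-min
chase. One top-level seed feeds deterministic substreams, so identical
parameters give byte-identical tables.

What the generator does **not** emulate: rifampicin penetration lag,
amplification-efficiency deviations from 2, inter-run calibration
drift, probe-level microarray effects, or biological variance beyond
the per-well Ct noise. Passing tests therefore demonstrate correctness
of the inference chain under the stated error model, not robustness to
every artifact of real qPCR.

The planted-sequence generator (`simulate_sequence_with_sites`) draws
background residues from {C, G} only, so planted AU-clamp motifs and
the planted U-tract are provably the only rule matches — a fixture
property for scanner validation, not a model of real base composition.

## Site scanning and end clustering

Coordinates are 1-based with the TSS at +1; bond b is the
phosphodiester bond between residues b and b+1. The +2U rule tests
residue b+2; the −3/4A rule tests residues b−2 and b−3 (the third and
fourth nucleotides upstream of the bond). The source convention for
counting upstream offsets is ambiguous (bond-based vs fragment-end-
based); the bond-based choice here is applied consistently and stated
in every output header. Bonds are scanned where both the +2 and at
least the −3 context exist; scanning is single-strand (RNA). U-tracts
are maximal runs of ≥ 6 U by default, the minimal stretch acting as an
entry site in the UTR studied. End clustering is greedy single-linkage
with max_gap = 10 nt, chosen so that end maps with internal gaps ≤ 10
and an inter-region gap of ~124 nt resolve into exactly two clusters.
BED output is 0-based half-open; a bond is written as the 2-nt interval
covering its flanking residues.

## Reporting precision

Fold changes ≥ 1 are reported to one decimal, < 1 to two decimals,
percentages to one decimal, all rounded half away from zero. Internal
arithmetic is always on unrounded values; rounding happens only at
report emission (rounding first would give 6.5 × 0.4 = 2.6 where the
unrounded product is 2.85 → 2.9). When a published table was itself
computed from unrounded fit values, reconstruction from its *rounded*
entries can differ in the last digit — e.g. rounded inputs give a UV
termination of 64.9% against a published 65.3%, and 7.2/3.1 = 2.32
against a published decay FC of 2.2. The package reproduces published
values exactly where rounded inputs suffice and otherwise reports the
value its inputs imply.

## Known limitations

- **Precision of the termination fraction at low f.** Since
  f̂ = 1 − (1 − f)/R with R the estimated decay-constant ratio, the
  absolute error scales with (1 − f). At f ≈ 0.96 the estimate is
  extremely robust (±0.004 in ≥ 95% of runs under the reference
  design). At f ≈ 0.65, a ±0.02 absolute error demands the λ ratio
  within ±5.8%; with σ_Ct = 0.15, four timepoints and six series the
  best achievable ratio SE is ~3.5–4% (this bounds *any* estimator on
  these data — the balanced-design log-OLS slope is the efficient
  one), so roughly one run in ten misses ±0.02 even with the efficient
  fit, and more with the default abundance-scale fit. Tightening
  requires more replicates or timepoints, not a better algorithm.
- Half-life estimates near or beyond the last chase timepoint (t½ ≳ 17
  min with a 30-min window) carry ~7% sampling spread under the
  reference design.
- The ΔΔCt chain assumes efficiency exactly 2; systematic efficiency
  deviations bias λ multiplicatively and cancel only partially in
  ratios.
- The termination formula presumes a single promoter; any internal
  promoter or processing that uncouples UTR and ORF synthesis breaks
  the 1 − 1/FCsynt reading.
- No RNA secondary-structure context in site scanning; the two
  positional rules alone over-predict sites on AU-rich sequence.
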