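# Methods

## The SAAID index

Two-photon microscopy of skin yields two co-registered signals per depth:
second harmonic generation (SHG), produced almost exclusively by
noncentrosymmetric fibrillar type I collagen, and two-photon-excited
autofluorescence (AF), dominated in the dermis by elastin. Their normalised
contrast,

    SAAID = (SHG − AF) / (SHG + AF),

the "SHG-to-AF aging index of the dermis", lies in [−1, 1]: −1 where only
elastin fluoresces, +1 where only collagen emits. Because it is a ratio of
channel sums it is invariant to any gain applied equally to both channels —
in particular to the depth-dependent pump-power ramp used to compensate
attenuation — but it is *not* invariant to channel-differential gain. The
package assumes the two detector channels are comparable as recorded and
exposes an optional per-channel gain (`TwoChannelStack.scaled`) for
sensitivity analyses.

### Per-depth statistic

Published SAAID work rarely states whether the index is computed from the
mean channel intensities of a frame or from per-pixel indices. The default
here is the **ratio of channel means** over the whole frame
(`statistic="channel_mean"`, `background_fraction=0`): it is the simplest
reading of the definition and is exactly invertible, which makes the
synthetic generator's round trip an identity. Two robustness options exist:
discarding the dimmest fraction of pixels by combined intensity before
averaging (`background_fraction`), and the median of per-pixel indices over
lit pixels (`statistic="pixel_median"`). A depth where SHG + AF is exactly
zero carries no index; it is reported as missing (NaN), never as zero,
because zero is a meaningful index value.

### Aggregation

Five image stacks per animal are technical replicates; animals are the
biological replicate. `aggregate_group(level="animal")` therefore first
averages stacks within animal and then takes the mean and sample SD
(ddof = 1; SD fixed to 0 when n = 1) across animals, so the reported n is
the number of animals (5 in the emulated design). `level="stack"` pools all
stacks instead. Missing depths are excluded per depth with n decremented.

## Synthetic data generator

No public imaging data exist for this design, so every downstream stage is
validated against a generator with known ground truth.

**Imposed means.** Given a target profile s(d) and total intensity T(d), the
expected channel means are SHG = T(1+s)/2 and AF = T(1−s)/2 — the exact
inverse of the index. Each rendered frame is rescaled so its *sample* mean
equals the expected mean, hence with noise disabled the profiler recovers
the target to floating-point round-off. The index is imposed on channel
means (the profiler's default statistic); per-pixel index distributions are
emergent, not controlled.

**Texture.** The SHG channel is an oriented-filament field: anti-aliased
line segments whose orientations follow an axial von-Mises law with
concentration κ = 12c/(1−c) for coherence dial c ∈ [0, 1]; c ≈ 0.1 mimics
the blurred, disorganised collagen of early granulation tissue and c ≈ 0.9
the aligned, cross-linked fibres of late remodelling. The dial is
recoverable: the coherence of the frame-averaged gradient structure tensor
is strictly increasing in c (verified over seeds in the test suite). The AF
channel is an independent smooth log-normal blob field. Texture is chosen
for testability, not optical fidelity: there is no PSF, scattering, or
photosensitizer chemistry.

**Noise and replicate structure.** Per-pixel noise is mean-one log-normal
(sigma 0.25) times the frame plus additive Gaussian detector noise (SD 2 on
~1000-unit intensities), clipped at zero. Replicate scatter enters as a
Gaussian shift of the whole SAAID profile per animal (SD 0.03 index units)
plus a smaller per-stack shift (SD 0.01). The animal SD is the calibration
that matters: with five animals the group-mean standard error is
0.03/√5 ≈ 0.013, so a ±0.05 recovery band sits at ≈3.7 SE — wide enough to
pass in ≈99% of realisations while keeping group SDs clearly non-degenerate
and in the visual range of published depth-profile error bars. These are
free parameters of the generator, not measured values; no per-depth SDs are
available in print to validate them against.

**Seeding.** Every stack's generator derives from
`SeedSequence((master_seed, group_index, animal_index, stack_index))`, and
the animal effect from a parallel sequence, so cohorts are bit-reproducible
and two groups with identical truths still receive independent noise.

**Healing model.** Wound areas decay as S(t) = S₀·exp(−rate·t) — the
simplest monotone model consistent with the published group courses, which
report no fit of their own. The preset rates come from ln(S₀/S₁₄)/14 on
those courses: control 0.168/day (≈90% closure by day 14), phototherapy
groups 0.216–0.313/day. Diameters are drawn by splitting the true area into
an ellipse with aspect ratio uniform in [1.0, 1.2] and multiplying each
diameter by 1 + N(0, cv), cv = 0.03 by default; major/minor ordering is
re-enforced after noise. The caliper's 0.02 mm resolution is recorded as
metadata and deliberately not propagated.

## Exact Mann–Whitney test

At n = 5 per group, asymptotic rank tests are unreliable and ties from
averaged profiles are possible, so the default is the exact permutation
test: all C(n₁+n₂, n₁) assignments of the observed pooled values are
enumerated (midranks make the enumeration tie-exact). The reported U is the
x<y pair count (half-credit for ties) minimised with its mirror n₁n₂ − U.

**Two-sided convention.** The p-value is twice the *smaller* of the two
tail masses including the observed statistic, capped at 1. With ties and
unequal group sizes the permutation distribution of U is not symmetric, and
doubling a fixed (lower) tail of the minimised statistic would make
p(x, y) ≠ p(y, x); the smaller-tail convention is provably symmetric
because swapping the groups maps the distribution onto n₁n₂ − U exactly.
Consequences at n₁ = n₂ = 5: the smallest achievable two-sided p is
2/252 ≈ 0.0079, and p < 0.05 requires U ≤ 2 — a nearly complete separation
of the groups. The empirical type-I error at α = 0.05 is therefore ≈0.03,
below nominal (verified by simulation). `mode="auto"` switches to a
tie-corrected normal approximation with continuity correction when the
enumeration would exceed 20,000 assignments.

No multiplicity adjustment is applied across depths or days by default,
matching common practice in this literature; Holm's step-down is available
via `adjust="holm"`. Mixed-effects modelling of stack-within-animal
correlation is out of scope (stacks are averaged within animal instead).

**Sensitive-depth localisation.** `sensitive_depth` aggregates one or more
p-by-depth profiles as the mean log₁₀ p per depth and returns the
contiguous interval around the minimum whose aggregate stays within
log₁₀(factor) of it (factor 2 by default), breaking ties to the shallower
depth. A flat aggregate returns the whole tested range flagged as not
localised.

## Dose arithmetic

For a continuous source, fluence × spot area = power × time. Protocols
print power, fluence and time but rarely the spot area, so
`spot_area_from_exposure` back-solves it from one printed triple; the
consistency of a second triple from the same source is then a pure
linearity check (4× the fluence at fixed power takes exactly 4× the time:
225 s → 900 s at 5 mW).

## Problem sizes and numerical choices

Simulated rasters are 32–64 px laterally rather than the instrument's 512:
the channel-mean statistic is unbiased at any raster size, and smaller
frames let the Monte-Carlo checks (50-seed recovery, 200-replicate null
calibration, 20-seed pattern recovery) run in tens of seconds. Depth grids
are 0–80 μm in 4 μm steps (21 depths) except the null calibration, which
uses 5 depths at 16 μm spacing since the null is depth-exchangeable.
Profile presets are piecewise-linear interpolations through a few knots per
condition. Exact-test ties are resolved by midranks; equality thresholds in
the enumeration use a 1e−9 slack to absorb float noise in rank sums.

## What passing tests do and do not show

The synthetic generator reproduces the *structure* of the study — group
sizes, stack counts, depth grid, profile shapes, closure courses — with
noise whose magnitude is a documented choice, not a measurement. Passing
recovery and calibration tests shows the pipeline is correct and
well-calibrated under that model; it does not certify the noise model
against real dermal imaging, nor validate channel gain matching,
registration quality, or ROI selection effects in real acquisitions.
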