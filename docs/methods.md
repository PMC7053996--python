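# Methods

`spinedyn` analyzes longitudinal two-channel fluorescence measurements of
dendritic spines: a pH-sensitive SEP-GluA1 signal reporting surface AMPA
receptor content, and a pH-insensitive dsRed2 cell fill whose spine
intensity proxies spine size and whose dendritic-shaft intensity serves
as the normalization reference. Because no public raw dataset accompanies
this kind of in vivo experiment, the package ships a calibrated
generative model that emulates the statistical structure of such data;
every analysis stage is exercised end to end on simulated inputs.

## Quantification model

For each spine at each imaging session, three regions of interest are
measured in each channel: the spine head, the adjacent dendritic shaft,
and a nearby background region of matched size. The elementary measure
is

    value = (spine_ROI − background_ROI) / (shaft_dsRed_ROI − background_ROI)

computed with the green spine ROI for sGluA1 and the red spine ROI for
spine size. Any multiplicative per-session imaging gain (laser power,
window clarity) scales all ROIs of a session identically in both
channels and cancels exactly in this ratio; the test suite asserts this
to floating-point identity for power-of-two gains.

Degenerate measurements are kept but flagged rather than silently
dropped: a non-positive background-subtracted numerator is floored at
ε = 10⁻⁶ and flagged (`floored_numerator`); a non-positive denominator
yields a missing value (`invalid_denominator`). Flagged values propagate
as missing through every downstream normalization — no imputation
anywhere.

Further normalizations re-express a spine's per-session ratios:

- **to_day1** — divided by the spine's first-session value,
- **to_baseline_mean** — divided by the spine's mean over the three
  pre-deprivation baseline sessions (spines missing any baseline session
  are excluded and logged),
- **to_dendrite_mean** — divided by the arithmetic mean over valid
  spines of the same dendrite at the same session (we read "average
  level of the dendrite" as the arithmetic mean; the geometric mean is
  reserved for the explicitly named per-dendrite change summary),
- **daily_change** — divided by the previous day's value, emitted only
  for transitions between consecutive calendar days with both values
  valid; transitions spanning a gap or the 4-day interval before the
  final deprivation session are omitted.

Per-dendrite summaries are geometric means over the spines present at
every session (the "persistent" population, matching how timecourse
figures are computed from such data).

## Session schedules

Two layouts: `baseline10` is ten consecutive daily sessions D1–D10;
`deprivation` is three daily baselines BL1–BL3 followed by imaging 1, 2,
3 and 7 days after binocular enucleation (VD1, VD2, VD3, VD7) or
time-matched sham surgery.

## Generative model

One NumPy `default_rng` stream seeded from the configuration drives the
whole simulation, giving a documented guarantee that identical
(config, seed) reproduce byte-identical datasets.

**Spine census.** Each dendrite starts with a Poisson (optionally
negative-binomial) number of spines, mean 15 by default. Every present
spine survives to the next session independently with probability
`survival_per_session`; elimination is permanent. New spines form at
`formation_rate` per dendrite per session (default 0.15) and then follow
the same survival process. The survival defaults are calibrated so the
fraction of first-session spines persisting across ten sessions matches
the reported layer-specific persistence: 0.958⁹ ≈ 0.68 for L2/3 and
0.955⁹ ≈ 0.66 for L5. Because later-formed spines cannot span the full
window by construction, the persistence statistic uses first-session
spines as its denominator — the population a longitudinal survival
measurement actually follows.

**Intensities.** Each spine has a lognormal sGluA1 set-point
(`baseline_log_mean` = −0.2, `baseline_log_sd` = 0.45 on the natural-log
scale, i.e. typical shaft-normalized ratios around 0.8 with wide
spread) and a size set-point whose log correlates with it at
`size_coupling_rho` = 0.7. Baseline sGluA1 additionally rises with
relative branch distance (log-slope `baseline_distance_coupling` = 0.3),
reproducing the distance-dependent baseline scaling seen in both layers.
Day-to-day variation is i.i.d. multiplicative lognormal noise around the
set-point, with σ chosen so the lognormal CV equals `fluctuation_cv`
(0.25 for L2/3, 0.15 for L5 — the layer ordering of spine dynamics). The
same daily shocks are correlated between channels at `size_coupling_rho`,
so daily size changes and daily sGluA1 changes correlate as observed.
An i.i.d. process is the simplest one matching a target CV together with
a stable day-1-to-day-10 correlation of relative levels; no
autocorrelation structure is claimed by the data we emulate, so none is
modeled.

**Transient spines.** Non-persistent spines sit at `transient_level`
(0.55) of a persistent set-point and ramp: ×0.5 at the formation
session and ×0.75 the next; symmetrically ×0.75 then ×0.5 into
elimination. This matches, qualitatively, the gradual rise of sGluA1
after formation and its decline before elimination, makes transient
spines dimmer than persistent neighbours, and gives them a higher CV.

**Imaging gain and noise.** One multiplicative gain per session
(lognormal, σ = `session_gain_sd` = 0.1) scales every ROI of that
session in both channels — channel-specific gains are unidentifiable
under shaft normalization and are omitted. Raw ROI values are
`gain × (signal + background_level) + N(0, noise_sd)` with
`background_level` = 50 and `noise_sd` = 2 in arbitrary units against a
shaft intensity of ~300.

**Deprivation effects.** Each dendrite (or each cell, for the L5 preset,
where classification is reported per cell) belongs to a "decrease" or
"no-decrease" subpopulation with probability `decrease_fraction`. On
post-deprivation sessions, latent sGluA1 is multiplied by a per-session
effect specific to (subpopulation × compartment), further modulated
along the dendrite by `(1 + depth_gradient × relative_depth)`; baseline
sessions are always multiplier 1, so sham and baseline data carry no
depth signal. Spine size follows the same effect at half the log
magnitude (square root), reflecting the smaller structural changes.
Post-deprivation fluctuation CV may differ from baseline
(`fluctuation_cv_post`): it drops to 0.18 for the L2/3 deprivation
preset and rises to 0.21 for L5, encoding the observed redistribution of
dynamics across layers after vision loss.

Preset effect profiles over (BL1 BL2 BL3 VD1 VD2 VD3 VD7):

| preset | arm | profile |
|---|---|---|
| L23_VD | apical, decrease | 1 1 1 0.65 0.85 1.0 1.0 (dip, recover) |
| L23_VD | apical, no-decrease | 1 1 1 1.0 1.05 1.1 1.3 (late potentiation) |
| L23_VD / L23_VD_basal | basal, both | 1 1 1 1.15 1.25 1.35 1.5 (early, larger) |
| nonV1_VD | apical, both | 1 1 1 0.95 0.90 0.88 0.85 (systematic decrease) |
| L5_VD | apical, decrease | 1 1 1 0.80 0.85 0.95 1.0 |
| L5_VD | apical, no-decrease | 1 1 1 1.0 1.02 1.05 1.08 (no significant rise) |
| GRIP1KO_VD | apical, both | 1 1 1 0.85 0.85 0.88 1.0 (dip, recover, no rise) |

Magnitudes were fixed once from the qualitative directions and rough
effect sizes the figures display (e.g. decrease dendrites must fall at
least twice the 18% classification threshold at VD1 so the rule is
identifiable above fluctuation noise) and are not fit to any data.

**Geometry.** z is depth below the pia in µm, increasing downward.
Apical segments are drawn at 30–120 µm, basal at 150–300 µm. A segment
is a straight 30–60 µm line with a random depth slope in ±0.8 µm/µm;
spines sit at sorted uniform arc positions, so spine depth is affine in
branch distance within a segment — exactly the confound the
ascending/descending analysis is designed to break.

**What the generator does not emulate**: optics (blobs are Gaussians,
no PSF model), motion artifacts, photobleaching, registration errors,
autocorrelated day-to-day dynamics, or spine morphology beyond the
red-intensity size proxy. Passing tests therefore validate the analysis
logic and its calibration against a known ground truth, not performance
on real imaging data with those additional failure modes.

## Analysis conventions

- **Fate classification.** A spine absent at an interior session but
  present before and after is treated as persistent with missing data (a
  detection failure), not as eliminated and re-formed; re-formation is
  not a process the emulated experiments describe.
- **Decrease / no-decrease rule.** A unit is "decrease" when its
  baseline-normalized sGluA1 at VD1 is ≤ 1 − threshold. The threshold is
  the sample SD of the sham group's relative change at VD1
  (`sham_threshold`), with the printed constants (0.18 dendrites, 0.435
  spines, 0.098 cells) available as fallbacks. It is a pure threshold
  rule — no per-unit hypothesis test, since the definition provides
  none. Units lacking VD1 are excluded from the percentage and logged.
- **Cell-level pooling (L5).** A cell's apical dendrites are pooled by
  geometric mean before applying the rule.
- **Basal/apical ratio.** Per neuron, dendrites are pooled by geometric
  mean per compartment; the ratio is basal over apical change, excluding
  neurons whose apical change is ≤ 0.05 (a guard against exploding
  ratios; exclusions are logged).
- **Orientation.** Ascending/descending uses the segment endpoints
  (|Δdepth|/Δdistance > 0.1, toward vs away from the pia), not a
  per-spine regression. Inverting the z axis flips the labels — the
  depth-below-pia convention is load-bearing.
- **Depth extremes.** Group size is `max(1, round(fraction·n))` with
  round-half-away-from-zero; z ties break by spine id for determinism.
- **Statistical routing.** Groups are Shapiro–Wilk-tested at α = 0.05;
  all-normal goes parametric (t tests, repeated-measures ANOVA with
  Bonferroni post hoc of each post-deprivation session against the
  pooled baseline), otherwise rank-based (Mann–Whitney, Wilcoxon,
  Friedman with Dunn's post hoc on within-unit ranks). Constant
  degenerate samples short-circuit to statistic 0, p 1 (equal) rather
  than NaN. Timecourse units are dendrites; CV and correlation units are
  spines.

## Problem sizes and tolerances

Simulated studies default to 6 neurons × 4 dendrites × ~15 spines;
calibration checks use ~1000 first-session spines (persistence), ≥ 500
persistent spines (CV recovery, ±10% relative, which also absorbs the
small-sample bias of an SD from ≤ 10 points), 100 apical dendrites
(decrease fraction, binomial CI), and 16 neurons × 200 replicates
(basal/apical ratio, ≥ 95% of replicates significant). The persistence
checks average five fixed-seed replicates so the ±3-percentage-point
band sits several standard errors from the expectation. These sizes were
chosen so each check is decisive at its stated tolerance while the whole
suite stays quick.

## Known limitations

- The "inverse-correlation" spine subset is operationalized as per-spine
  Pearson r < 0 over daily-change pairs (threshold configurable); the
  emulated studies give no exact criterion, so its reported fraction
  (~18% in vivo) is not a calibration target.
- CV windows for before/after-deprivation comparisons default to
  BL1–BL3 vs VD1–VD7 and are configurable; the emulated analyses do not
  pin these windows down.
- Whether the size (dsRed) channel shares the green channel's background
  ROI is not specified by the emulated workflow; the generator and
  quantifier assume separate background ROIs per channel with identical
  statistics.
- The renderer is a visualization and round-trip testing aid, not an
  optics simulation; spine pixel positions are laid out at uniform
  spacing in branch-distance order so that ROI masks never overlap.
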