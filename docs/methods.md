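# Methods

## The measurement problem

Laminar *Ulva* blades grow vegetatively from any excised piece, so a
circular disc cut from a thallus and held flat under a mesh expands in
all directions. Top-down time-lapse imaging of many discs in parallel
turns growth screening into an image-analysis problem: segment each
disc in each frame, convert pixel areas to mm², and reduce the area
trajectory to interpretable growth parameters. This package implements
that reduction plus the downstream physiology (night carbon budget,
diurnal metabolite screens), with a simulator standing in for the
physical rig so that every stage can be validated against known truth.

## Growth model and rate definitions

Within each photoperiod phase a disc is assumed to grow exponentially
with an instantaneous rate switch at lights-on/off:

    A(t) = A0 · exp(g_day · τ_day(t) + g_night · τ_night(t))

where τ are elapsed phase times in periods and g are per-period log
rates. All reported rates are *specific* (logarithmic) rates:

- Area SGR per phase occurrence: 100 · ln(A₂/A₁), % per period.
  Log rates are the only formulation in which day SGR + night SGR
  equals the 24-h SGR identically, which is what a stacked day/night
  bar decomposition of daily growth presumes. A simple-percent variant
  (100·(A₂/A₁ − 1)) is available via `method="simple"` but is not
  additive.
- RGR = ln(W₂/W₁)/t, mg·mg⁻¹·d⁻¹, from start/end dry weights.
- SLA = area/DW (mm²·mg⁻¹, time-averaged area and mean of start/end
  DW); NAR = RGR/SLA, so RGR = SLA × NAR holds identically. The
  classical integral NAR is not computable from two weight points.
- Water content = (FW − DW)/FW.

A multi-day phase SGR is the arithmetic mean over complete phase
occurrences (six for a six-day run); by telescoping, the mean daily
SGR equals the whole-span log rate divided by the number of days.

## Imaging pipeline

**Consensus.** Frames are grouped into half-open 30-min windows
anchored at the experiment start and averaged per pixel (sequence
mean), which suppresses water-movement noise by √n; the consensus
timestamp is the window midpoint.

**Segmentation.** Per well (pixels outside well circles are ignored):
an Otsu threshold is computed on the intensity histogram (excess-green
2G−R−B for RGB input), then re-anchored at the midpoint of the two
class means — the midpoint is stable across windows, so the included
anti-aliased edge ring does not wander frame to frame, which matters
because rate estimates are ratios of areas at nearby times. Mesh-line
gaps are bridged by morphological closing (disk radius = expected
thread width, default 1 px) plus hole filling; the largest connected
component is kept. Because discs are convex, occluded pixels are then
recovered by adding *background-level* pixels inside the component's
convex hull; mid-level edge pixels are deliberately not added, so the
hull repairs mesh notches without inflating the rim (naive hull pixel
counting overestimates a digitised circle by 2–4%). Wells whose
foreground/background contrast falls below 0.08 (on a [0,1] intensity
scale) are reported empty rather than raising. On clean rendered discs
this estimator is accurate to a few tenths of a percent for radii
≳ 15 px; under the full default noise model the per-window error is
roughly ±1%.

**Phase anchoring.** Consensus samples never sit exactly on a phase
boundary. Each boundary is anchored by a short log-linear regression
over the ending phase's samples within a tolerance window (default: a
quarter phase) extrapolated to the boundary time. Within a phase,
log-area is linear in time under the growth model, so this is exact on
noiseless data, is not biased by the rate change at the boundary (an
interpolation across the kink is), and averages segmentation noise.
Consecutive phases share their boundary anchor, so day + night = daily
holds to machine precision on any series.

**QC.** Points flagged by segmentation or deviating more than 3× from
a centred rolling median are masked; a series with more than 20%
masked points is excluded with reason "insufficient valid points".
These thresholds are artifact choices — the exclusion criteria of real
screens are rarely published.

## Night carbon budget

Assuming night expansion produces as much biomass per percent of area
growth as day expansion (supported by stable water content across the
diurnal cycle), the daily RGR is apportioned to the night by the SGR
ratio:

    RGR_night = RGR_daily × (SGR_night / SGR_daily)
    OM_night  = RGR_night × (1 − ash/100)
    C_required = RGR_night × c × f        (c = 0.30, f = 1.39)
    C_supplied = (Δstarch + Δsucrose) × 6 × 12.011 µg/µmol × 10⁻⁶
    C_missing  = C_required − C_supplied

Ash is the inorganic combustion residue (% DW); c is the carbon
fraction of dry biomass; f the growth respiration factor (carbon
respired per unit of structural carbon laid down); carbohydrate deltas
are end-of-day minus end-of-night pools in µmol glucose equivalents
per g DW, so net overnight synthesis yields a negative supply. The
demand is computed from the total night biomass increase rather than
the ash-corrected organic matter: that convention reproduces the
published aggregate chain (0.137 × 0.30 × 1.39 = 0.057) whereas the
OM basis does not; both the constants and the basis are configurable
(`assemble_budget(..., basis="om")`), and the OM column is still
reported. Aggregates are means of per-strain values; the headline
supplied fraction is 100 × mean(supplied)/mean(required).

## Metabolite statistics

Turnover is the signed EOD − EON difference (positive = consumed
overnight). The night-consumption screen ranks metabolites by
log₂(mean EOD / mean EON) across strains with a default cutoff of 1
(two-fold); zero means are offset by half the smallest nonzero value
of that metabolite so the ratio stays defined without discarding
strains. Associations with growth are Spearman rank correlations
(average ranks; two-sided p from the t approximation) computed
pairwise-complete; constant variables yield an undefined (NaN) rho.
Multiple testing is corrected per family — one family per correlation
matrix, and one per timepoint set (EOD, EON, overnight difference) in
the biomarker screen — with Benjamini–Hochberg q-values by default; a
Storey π₀-scaled variant (cubic smoother of π₀(λ) over λ ∈
[0.05, 0.95], evaluated at the largest λ) is available as
`fdr="storey"`. π₀-estimating methods are less conservative, so hit
lists at q < 0.05 are method-sensitive; the method used is recorded in
every CLI run's output.

Because everything is rank-based, screen decisions at EOD/EON are
invariant under strictly monotone transforms of the abundances — an
important property for semi-quantitative GC-MS data.

**Known limitation — small-n tail calibration.** At n = 16 strains the
t approximation to the Spearman null is anticonservative in the
extreme tail (direct Monte Carlo: P(min of 47 null p-values <
0.05/47) ≈ 0.063 vs 0.049 nominal), so the per-family probability of
at least one false hit under a global null is ≈ 0.065 rather than
0.05. The fraction of pairs flagged remains far below the nominal
level, and the planted-effect recovery tests are unaffected, but
p-values near the significance boundary at this sample size should be
read with that inflation in mind.

## Simulator scope and defaults

The generator's defaults encode the study conditions: 12 h:12 h
photoperiod, 5-min frame interval, 6-day runs, 36 discs per tank
(6×6 well grid, 35 mm wells), ~12 mm initial disc diameter (4% CV),
0.35 mm/px calibration. Strain-level rates are drawn around the
aggregate observed values — day SGR 4.837 ± 1.99, night SGR
8.636 ± 3.265 % per period, RGR 0.209 ± 0.062 mg·mg⁻¹·d⁻¹,
night/daily SGR ratio 65.45 ± 10.8%, ash 23.07 ± 4.14% DW — with a
0.5 pp within-strain disc spread. Panels put starch ~50× sucrose at
end of day (sucrose 10 µmol glc-eq/g DW), consume ~55%/50% of
starch/sucrose overnight, accumulate nitrate at night (log-normal
around 2.5 mg N/g DW, ~48% CV) log-coupled to true RGR with
configurable strength, and consume ~80% of it by day. The metabolite
matrix spans a fixed 47-name catalogue (20 amino acids, 14 organic
acids, 13 carbohydrates/polyols — only the biomarker names are fixed
by the study system; the rest is a synthetic stand-in); planted
biomarkers default to glycine/methionine positive and threonic acid,
myo-inositol, raffinose negative at EOD, glycine/arginine positive and
threonic acid negative at EON, at a target Spearman strength of 0.9;
17 metabolites are planted as night-consumed (4-fold drop).

Imaging noise has no published characterisation, so its defaults are
free parameters chosen to be plausible for a low-cost camera rig:
additive pixel noise sd 0.02 (on [0,1]), per-frame translation jitter
±1.5 px, multiplicative flicker sd 3%, and a background-coloured mesh
grid of 9 px pitch (3 mm) and 1 px thread (0.35 mm — a thicker thread
would occlude more of the disc than a real plankton mesh does). All
randomness derives from one integer seed with fixed per-strain,
per-disc and per-metabolite substream offsets, so outputs are
bit-for-bit reproducible. Discs grown past the well wall are clipped
and flagged in metadata, not raised.

What the simulator does **not** emulate — and what passing tests
therefore cannot show about real data: tissue texture and translucency
gradients, non-circular disc outlines, wounding responses and
sporulation, biofouling, camera vignetting and perspective, and any
correlation structure among metabolites beyond the planted effects.
Recovery results on synthetic stacks bound the *algorithmic* error of
the pipeline, not the biological measurement error of a physical
platform.

## Problem sizes in the test suite

The end-to-end recovery test uses 3 strains × 12 discs × 6 days at the
default calibration (≈1700 frames of 642² px); screen calibration uses
500 null simulations and 100 planted simulations at 16 strains × 47
metabolites; oracle equivalence checks 1000 random small samples.
These sizes keep the full suite in the minutes range while leaving
Monte-Carlo error well below the tested tolerances.
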