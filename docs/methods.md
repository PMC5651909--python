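# Methods

## Synthetic tissue generator

**Mesh.** Cell sheets are Lloyd-relaxed (4 iterations) bounded Voronoi
tilings: seeds are mirrored across the field boundary so every region is
finite, giving centroidal, round-ish polygons that tile the field exactly.
Interior junctions are the Voronoi ridges between seed pairs; boundary
segments are edges with a single adjacent cell.  Clusters (migrating
border-cell rosettes, 6–8 cells) place one central seed and a ring inside
a disc, with the ring cell at angle 0 along +x as the unique leading cell.
Coordinates are (row, col), origin top-left, pixel units; the default
field is 512×512 px at 0.2 µm/px, so a 20 µm² ROI is 500 pixels.

**Ground truth.** Each junction carries a true FRET efficiency E ∈ [0,1].
Patterns: `uniform` (all junctions equal), `radial` (a linear ramp from
E_high at the centre — compressed, low-tension cells — to E_low at the
stretched periphery), and `front_back` (all junctions of the leading cell
at E_low, the rest at E_high).  The map from molecular tension to E is not
modelled; E is parameterized directly because the ratiometric index is
semi-quantitative and every downstream claim is about monotone recovery,
not radiometric calibration.

**Photophysics.** A membrane pixel with sensor density ρ and local
efficiency E produces mean counts

    I_CFP  = ρ·Q_D·(1−E) + bg
    I_YFP  = ρ·Q_A + bg
    I_FRET = ρ·G·E + α·ρ·Q_D·(1−E) + β·ρ·Q_A + bg

with defaults Q_D = 1200, G = 2400, Q_A = 1800 counts per unit density,
bg = 20 counts/slice, α = β = 0.10 (the 0.05–0.15 regime typical of CFP/YFP
pairs on confocal systems).  Membrane fluorescence is a ridge along each
junction with a Gaussian cross-profile (width 3 px, σ = width/3); where
ridges meet, the nearest junction's E wins, so each pixel has one truth
value.  Acquisition adds z-slices (3 by default, out-of-focus slices
attenuated ×0.5 per step), optional Poisson noise, and clipping at
2^bit_depth − 1 (16-bit default) with the clip count reported.  Identical
seeds give bit-identical stacks.  Calibration genotypes reuse the same
geometry with the donor or acceptor absent, or with both present on
separate molecules (sensitized term zero).

**Pulsing.** Apical pulsing modulates per-cell area sinusoidally
(period 240 s, amplitude 15 % by default, per-cell phase).  The mesh is
deformed by a smooth warp in which every cell acts as a Gaussian
divergence source of its own radius, scaled to the requested area change
and damped to zero at the field boundary.  Because the warp is a function
of position only, shared vertices stay shared (the tiling cannot tear)
and the total tiled area is conserved exactly.  Per-cell achieved
amplitudes are attenuated relative to nominal where neighbours pulse in
antiphase — as in a real confluent sheet, where area is exchanged, not
created.  A lightweight record-level generator produces analytic area
trajectories (8 time-points at 60 s) with optional measurement noise and
an optional coupling of the index to the pulsing phase (difference
`delta_e` between fully contracted and expanded states, contracted
lower) — the positive control a functional tension sensor would show.

**Decays.** TCSPC histograms are sums of exponentials convolved with a
Gaussian IRF, evaluated in closed form (exp·erfc, computed via `erfcx`
for stability), scaled to the photon budget and Poisson-sampled.  The
default grid is 256 bins × 97 ps ≈ 25 ns, matching a 40 MHz repetition
rate.

## Ratiometric pipeline

Preprocessing follows the standard confocal chain: 3×3 median filter per
slice, saturation flagging, rolling-ball background subtraction
(default radius 50 px), maximum z-projection.  Saturation is detected on
the raw counts *before* the median filter — an isolated saturated pixel
would otherwise be erased rather than flagged — and propagates to an
invalid-pixel mask excluded from all statistics.  For radii above 16 px
the rolling-ball background is estimated on a shrunken image and
rescaled (the classic ImageJ speedup); the estimate is clipped so
subtraction never produces negative counts.

The membrane mask is the AND of per-channel Otsu thresholds on CFP and
YFP (both fluorophores present; OR available).  Correction factors are
the median of pixel-wise ratios over the expressing channel's mask
(robust to Poisson outliers; a least-squares slope through the origin is
available, and the estimator used is recorded).  At least 100 mask pixels
are required.  Sensitized emission and the index follow the formulas in
the README; negative-SE pixels are marked undefined and excluded, never
zeroed, because zeroing would bias means downward.  The per-image summary
is the arithmetic mean over defined pixels.

Diagnostics: the index–intensity Pearson correlation (≈0 for a clean
ratio; positive when an unsubtracted additive term sits in the donor
channel) and a co-expression check that declares intermolecular FRET
detected only above a configurable noise floor (default index 0.01).

## Cell graph

Segmentation seeds a watershed at local maxima of the smoothed (σ = 2)
distance transform of the interior (sub-Otsu) region, one seed per
enclosed interior component — the segmented-particles convention, which
makes a closed membrane yield exactly one cell per enclosure.  The
watershed elevation uses a lighter smoothing (σ = 1) so ridge lines stay
on the membrane crest; the whole field is partitioned, so label areas sum
to the image area.  Segmentation is fully deterministic.

The graph stores per-cell area, centroid, orientation and elongation
(major/minor axis ratio from second-order moments) and per-edge
boundaries between label pairs.  Edge endpoints snap to junction vertices
(points where ≥3 labels meet); edge length is the Euclidean distance
between the two vertices — the convention used for the pulsed-edge
analysis — not the boundary arc length.  FRET overlay averages defined
index pixels within a band (default 3 px, the membrane width) of each
edge; a cell's membrane mean is defined as the pixel-weighted aggregate
of its edges' means, so the aggregation identity holds exactly.

Classification: cells are `elongated` iff elongation ≥ 1.5 (threshold
configurable, ties elongated); within each cell, edges at or above the
median length are `long` (per-cell median split; ties long).

## Dynamics

Pulsing-stage calls use eight 1-min area snapshots: t0 and t7 are in
different stages iff |A7−A0| exceeds both 10 % of A0 and one standard
deviation of all eight time-points (sample SD, ddof = 1; both
inequalities strict; the 10 % is referenced to the earlier time-point).
Edge calls compare two lengths 1 min apart with a strict 20 % threshold.
Both rules are pure functions and scale-invariant.  State comparisons
feed the FRET values of each record's two time-points, assigned to the
state the cell occupied, into Welch's test.

Front/back analysis projects cell centroids on the migration axis,
takes the extreme cells, and grows each ROI from the masked pixels of
that cell nearest its centroid until ~20 µm² is collected; the front and
back means and their ratio are always reported together.

## FLIM

Decays are fitted by Poisson maximum likelihood (TCSPC counts are
Poisson; least squares over-weights the bright peak and biases the tail),
with Nelder–Mead from several lifetime starting points and a Powell
polish.  Lifetimes are constrained to the measurement window — beyond it
they are unidentifiable and a runaway component would corrupt the
intensity-weighted lifetime.  Two-component fits with τ₂/τ₁ < 1.05 or a
vanishing amplitude are flagged degenerate; τ_AvInt remains well defined.
The IRF is estimated from the rising edge (centre at the half-maximum
crossing, width from the 10–90 % rise of a Gaussian CDF); this estimate
carries some bias into individual components at high counts, but τ_AvInt
and efficiencies are robust to it, and a measured IRF can be supplied
instead.  Lifetime maps pool counts 2×2 (configurable), skip superpixels
below a count threshold (default 100), and fit each pooled decay.
Periodic wrap-around of incomplete decays is not modelled.

## Statistics

Welch's t-test is implemented from the formula (cross-checked against
scipy in the tests), two-sided, with the star convention *** p ≤ 0.001,
** ≤ 0.01, * ≤ 0.05.  Effect size d = (μ₁−μ₂)/σ uses the pooled SD.  The
closed-form minimal detectable difference solves the two-sample
noncentral-t power equation for d*(α, power, n) by bisection;
MDD = d*·σ.  The permutation estimate draws k values without replacement
(k = 2…n, default 10,000 draws; tests use 1,000), averages the subsample
SD, and multiplies by d*(k); it is reported in index units and as a
percentage of the dataset mean (the "%" convention is ambiguous in the
field, so both are emitted).  Per-draw effect sizes are recorded as the
absolute standardized half-split difference — a null effect-size
distribution.  Because averaging SDs is slightly biased low (Jensen),
the permutation MDD sits a few percent below the closed form at small k;
the oracle-equivalence test therefore compares averages over several
datasets, feeding the closed form each dataset's own SD so the check
validates the machinery rather than one draw's sampling luck.

## Orchestrator

`RunConfig`/`run` stitch the stages in acquisition order for five
scenarios (`wing_disc`, `amnioserosa`, `border_cells`, `calibration`,
`decay`), write every table as fixed-precision CSV plus a JSON report
echoing the full configuration, and are byte-deterministic given the
seed.  The border-cell scenario takes cluster cell identities from the
ground-truth rasterization (ROI placement emulates choosing patches from
an overview image); all other scenarios segment from the rendered YFP
channel.

## Problem sizes and what the tests show

The test suite and acceptance script use 40-cell 256² images for
pipeline-level checks, the 100-cell 512² mesh for segmentation recovery,
20 seeds for null-honesty and power rates, 10⁵-photon decays for FLIM,
and 1,000-draw permutation curves — sizes chosen so the full validation
runs in a few minutes on one core while keeping every statistical check
comfortably powered.  Passing tests demonstrate correct recovery under
the generator's assumptions: piecewise-linear photophysics, Gaussian
membrane profiles, Poisson shot noise, sinusoidal pulsing, Gaussian IRFs.
They do not certify behaviour under structured autofluorescence, depth-
dependent scattering, photobleaching, chromatic misregistration or
non-Gaussian IRFs, none of which the generator emulates — on real data
the diagnostics (intensity correlation, saturation and exclusion
fractions, degeneracy flags) are the guard rails.
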