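# fretion

Quantification toolkit for FRET-based molecular tension sensors in
epithelial tissues, with a synthetic tissue-image generator that supplies
full ground truth.

## The problem

Genetically encoded tension sensors insert a donor–elastic-linker–acceptor
cassette (e.g. ECFP–(GPGGA)₈–mEYFP) into a force-bearing protein such as
E-Cadherin.  Tension stretches the linker, separates the fluorophores and
lowers the Förster resonance energy transfer (FRET) between them — so FRET
becomes a molecular-scale force readout at cell–cell junctions.  Measuring
it in a living, crowded epithelium is notoriously artifact-prone: spectral
bleed-through and cross-excitation contaminate the FRET channel,
autofluorescence and intensity variation bias ratiometric indices, and
underpowered comparisons can hide (or fabricate) tension patterns.

`fretion` implements the complete analysis chain for such experiments —
ratiometric sensitized-emission imaging, cell-graph statistics, pulsing
dynamics, TCSPC lifetime fitting, and a permutation power analysis — and
pairs every stage with a generator of synthetic microscopy data whose true
junctional efficiencies are known, so the chain's recovery properties are
testable end to end.

## The quantities it computes

With three acquisition channels `I_CFP` (donor excitation/emission),
`I_YFP` (acceptor/acceptor) and `I_FRET` (donor excitation, acceptor
emission), calibration genotypes give the correction factors
α = I_FRET/I_CFP (donor-only) and β = I_FRET/I_YFP (acceptor-only).
The sensitized emission and pixel-wise FRET index are

    SE = I_FRET − α·I_CFP − β·I_YFP
    FRET index = SE / (I_CFP + SE)

with negative-SE pixels deleted.  Lifetime imaging provides the absolute
efficiency from intensity-weighted lifetimes (τ_AvInt = Σaᵢτᵢ²/Σaᵢτᵢ of a
biexponential reconvolution fit):

    E = 1 − τ_sample / τ_donor

Group comparisons use Welch's t-test and Pearson's r; the minimal
detectable difference at significance α and power 1−β follows from the
standardized effect size d = (μ₁−μ₂)/σ via the noncentral-t power
equation, estimated both in closed form and by the permutation procedure
(repeated subsampling of a control dataset).  A cantilever spring-sheet
formula F = −(E·a³·b)/(4·L³)·d calibrates external tissue-stretching
forces.

## Worked example

```bash
python examples/01_render_and_quantify.py
```

```
mean FRET index          : 0.4002
analytic value for E=0.25: 0.4000
pixels quantified        : 8798
index-intensity Pearson r: -0.011
```

A 40-cell sheet whose junctions all carry true efficiency 0.25 is rendered
with Poisson noise and pushed through the full chain; the measured mean
index matches the generator's analytic value to three decimals, and the
near-zero index–intensity correlation confirms the ratio is
intensity-independent (the diagnostic that flags miscalibrated background
subtraction on real data).

The other examples cover calibration (`02`), cell-graph shape/edge
statistics (`03`), pulsing-state classification with the 10 % + 1 SD rule
(`04`), front/back ROI ratios in a migrating cluster (`05`), FLIM fitting
(`06`, recovering E = 0.09/0.12 from simulated decays), and the power
analysis (`07`).  A thin CLI wraps the same functions:
`fretion simulate --scenario wing_disc --seed 0 --out out/`.

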