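# Methods

This note documents the models, parameter choices and numerical decisions
behind `ampcyt`, and what the synthetic-data generator does and does not
emulate.

## Forward model

**Dielectrics.** Particles are spheres. Beads are homogeneous lossless
dielectrics; cells follow the single-shell model (cytoplasm sphere plus thin
membrane shell), reduced to an equivalent homogeneous complex permittivity
via the standard confocal-shell formula with γ = R/(R−d). The induced-dipole
contrast against the buffer is the Clausius–Mossotti factor
f_CM = (ε*_p − ε*_m)/(ε*_p + 2ε*_m). The complex transit amplitude at each
stimulation frequency is A_f = gain · (2R)³ · f_CM(f): at low frequency an
intact membrane makes a cell behave as an insulator (f_CM ≈ −0.5, signal ∝
volume), at high frequency the membrane is capacitively shorted and f_CM
probes the interior. All phases are reported relative to the bead
reference, which is non-dispersive (phase flat across frequency) — this is
both the physical rationale for bead phase calibration and the property
used to identify beads without labels.

**Pulse shape.** A transit through the three-electrode differential sensing
zone produces A·[g(t−t₁) − g(t−t₂)] with unit-peak Gaussian lobes. Lobe
separation is (electrode width + gap)/v and lobe width σ = width/(2v); one
velocity per event (no parabolic flow profile — see Limitations). With the
default geometry (30 μm electrodes, 10 μm gaps, 40×20 μm channel,
10 μL/min) the mean velocity is ≈0.208 m/s and the lobe separation
≈0.19 ms, about 22 samples at the 115 kHz demodulation rate.

**Disturbances.** Position-induced blurring (field non-uniformity across
the channel height) is modelled as a per-event multiplicative lognormal
magnitude jitter (relative sd 0.15) plus an additive Gaussian phase jitter
(sd 0.03 rad), one draw per event applied to all frequency channels; the
phase-jitter default reproduces the target bead-phase scatter of 0.03 rad.
Additive white Gaussian noise (rms 0.5 signal units per quadrature) gives
the smallest population (bacteria, |A| ≈ 11–14) a single-channel SNR above
20, before the ~5× matched-filter gain. Event arrivals are Poisson with
rate = concentration × flow rate; the default concentrations (2×10⁵
beads, 4×10⁵ bacteria, 3×10⁵ RBC per mL) give ≈150 events/s. Per-event
size is lognormal around the population nominal (CV: beads 1.5%, bacteria
6%, RBC 10%); velocities are lognormal with 5% CV.

## Dielectric parameter defaults (assumptions)

No cell or buffer dielectric values are measured inside this package; the
defaults are literature-typical values chosen once, by forward evaluation,
to reproduce the qualitative orderings the assay relies on. They are
plainly exposed as constants (`BUFFER_A`, `POLYSTYRENE_BEAD`,
`RBC_HEALTHY`, `RBC_DAMAGED`, `BACTERIUM_LIVE`, `BACTERIUM_DEAD`) and can
be replaced wholesale.

| particle | R (μm) | d (nm) | σ_mem (S/m) | ε_mem | σ_cyt (S/m) | ε_cyt |
|---|---|---|---|---|---|---|
| buffer (≈110 mM KCl) | — | — | σ = 1.3 | ε_r = 80 | — | — |
| bead (polystyrene, Ø4.5 μm) | — | — | σ ≈ 0 | ε_r = 2.55 | — | — |
| RBC healthy (H) | 2.9 | 5 | 1e−6 | 5.6 | 0.52 | 59 |
| RBC damaged (L) | 2.9 | 5 | 1e−3 | 5.6 | 1.15 | 80 |
| bacterium live | 1.5 | 15 | 1e−6 | 8 | 0.9 | 60 |
| bacterium dead | 1.5 | 15 | 1e−4 | 8 | 0.05 | 50 |

The damaged RBC raises membrane conductivity ~10³× (pore formation) and
moves the cytoplasm toward the suspending medium (hemoglobin release); this
drives its 20 MHz phase from ≈−0.15 to ≈−0.83 rad (bead-referenced) and
shrinks its high-frequency electrical diameter — the L subpopulation. The
dead bacterium instead models a permeabilized envelope with a rigidified,
peptide-bound cytosol (interior conductivity strongly reduced), which moves
its high-frequency phase *toward* the bead reference (≈−0.58 → ≈−0.06
rad); a "cytoplasm → medium" change, appropriate for RBC ghosts, would
move it the wrong way in this model.

**Peptide accumulation.** Dead bacteria do not jump to the fully-dead
signature: their amplitude is interpolated (geometrically, in the complex
log domain) between live and dead models with weight
s = 0.5 + slope·log₁₀(dose/K_kill), clipped to [0, 1] (slope default
0.25/decade, `DoseModel.accumulation_slope`; 0 disables). This makes the
median bacterial phase keep drifting for a decade beyond the kill
half-point and is what renders the impedance Hill slope much shallower
than the CFU killing slope. It applies to bacteria only; a lysed RBC
carries the full damaged signature from the start.

**Dose model.** Damaged fractions follow Hill laws with defaults
K_kill = 0.034 μM, n_kill = 2.7 (bacteria) and K_lysis = 0.15 μM,
n_lysis = 1.5 (RBC); the reference-assay generator (Poisson CFU counts,
absorbance between NC and PC levels with 0.01 absorbance noise) is driven
by the same model, so impedance-derived and reference curves share their
ground truth.

## Event processing

Detection correlates every channel with the nominal unit-norm bipolar
template, combines channel energies, and thresholds at 6 robust
standard deviations (1.4826×MAD) above the median, merging peaks closer
than 0.8 ms. Fitting uses variable projection: the solver (bounded
trust-region least squares) iterates only over (center, lobe separation,
σ) — shared across channels, since one particle makes one transit — while
each channel's complex amplitude is an exact linear solve. Initialization
is deterministic (detected peak time plus the geometric
separation/width); lobe inversion is unrepresentable because separation is
bounded positive, the amplitude sign absorbing it. Events with relative
RMS residual > 0.3 or truncated lobes (within 3σ of the window edge) are
rejected; coinciding transits fail the residual rule, which is the
package's whole treatment of coincidences.

Feature definitions: electrical diameter |A_f|^(1/3) (arbitrary units
until calibration), phase arg A_f wrapped to (−π, π]. At moderate SNR the
fitted |A| carries a small positive second-order bias (the three nonlinear
timing parameters adapt to noise); it is below 0.5% at SNR 20 and largely
cancels in bead-calibrated ratios.

## Calibration and gating

Bead identification ranks low-frequency diameter modes by the median
cross-frequency phase range of their members (computed wrap-safely — raw
bead phases sit near ±π) and requires the winner to be non-dispersive in
an absolute sense (< 0.05 rad across channels; beads scatter ~0.01 rad,
the least dispersive cells ~0.11 rad). A sample without beads therefore
fails calibration rather than calibrating on cells. The winning mode is
refined by a ±20% diameter window and a 0.12 rad phase window, and at
least 10 beads are required.

Calibration multiplies each frequency's diameters by (4.5 μm / mean bead
diameter) and shifts phases so the mean bead phase is exactly zero; phase
centring is done in two passes (circular mean, then arithmetic mean of the
centred values) so the set-point holds to machine precision despite the
±π wrap. The transformation is applied uniformly to all events and is
idempotent.

Gating: non-bead events below 3.8 μm electrical diameter at 0.5 MHz are
bacteria, at or above it RBCs (boundary to RBC, documented tie rule). The
H/L split fits a deterministic two-component Gaussian mixture to the
20 MHz phase (components seeded at the 10th/90th percentiles, fixed
random state). If the component means are closer than 2.5× the sum of
their widths the sample is declared unimodal (a half-split of a single
Gaussian lands at ≈1.3×, genuine H/L modes at >5×) and events are
classified against a fixed threshold instead (default −0.5 rad, the
midpoint of the typical calibrated H and L phases above). Dose-series
analysis (`build_impedance_killing_curve`) always uses a fixed threshold
anchored at the midpoint of the NC and PC median phases, because the NC
and PC samples of a series are expected to be unimodal.

## Dose–response

All four readouts are mapped to a common 0–100% axis anchored at the
negative control (NC, untreated) and positive control (PC, saturating
peptide for bacteria, osmotic shock for RBCs): killing % from CFU counts,
hemolysis % from absorbances, and min–max normalizations of the median
bacterial phase and of f_L between their NC and PC values. Median (not
mean) phase is used; interquartile ranges are reported alongside. The Hill
model is fitted by unweighted nonlinear least squares (lmfit), K₀ = the
positive dose nearest 50% response, n₀ = 1, with standard errors from the
fit covariance; at least three distinct positive doses are required,
NC enters as a data point at x = 0 (where the model is exactly 0), a
finite-dose PC as a data point, an osmotic PC only as an anchor.

## Problem sizes and reproducibility

Default runs use 3–5 s streams per sample (≈250–750 events at the nominal
concentrations), which puts Monte-Carlo error on f_L near 0.03–0.04 per
sample and lets a full three-series assay (18 samples) complete in a few
minutes on one core; longer streams shrink the error as 1/√N without any
other change. One integer seed governs a run; per-sample seeds are derived
from it and the sample name (CRC-based, < 2³¹), so staged and single-pass
executions are byte-identical.

## What the generator does not emulate

* No finite-element electrode field: position blur is a statistical model,
  not a field map; there is no correlation between blur and transit
  velocity, and no double-peaked amplitude structure from off-centre paths.
* One velocity per event — no parabolic profile, no lobe asymmetry.
* No double-shell or ellipsoidal cells (bacterial wall and membrane are
  lumped into one shell; real *Bacillus* are rods, not spheres).
* Coincidences are generated but never resolved — only rejected.
* Electronic non-idealities (drift, 1/f noise, crosstalk between
  demodulation frequencies) are absent.

Passing tests therefore demonstrate the correctness of the processing
chain under the stated event model and realistic rates/SNR, not robustness
to every artefact of real instrument data.

## Known limitations

* The dielectric defaults are assumptions; only the qualitative phase
  orderings they produce are asserted, and all quantitative recoveries are
  against the generator's own ground truth.
* The blind mixture H/L split needs well-separated modes; heavily
  overlapping subpopulations fall back to the fixed threshold with a
  warning.
* Detection assumes the nominal velocity within ~±20% for the matched
  filter; grossly slower/faster particles lose matched-filter gain.
* Electrical diameter is a dielectric quantity: it equals geometric size
  only up to the |f_CM|^(1/3) factor, which is why the damaged-RBC
  electrical diameter shrinks at high frequency while the cell does not.
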