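# ampcyt

Single-cell **microfluidic impedance cytometry** analysis for antimicrobial
peptide (AMP) assays: a tested, reusable pipeline that quantifies AMP
bactericidal activity on bacteria and toxicity to red blood cells (RBCs)
from label-free electrical signatures, together with a physically motivated
synthetic-data generator so that every stage can be exercised and validated
without instrument data.

It is aimed at researchers developing impedance-based antimicrobial
susceptibility tests (AST): membrane-permeabilizing peptides change a cell's
dielectric properties within minutes, so the impedance phase at high
frequency (11/20 MHz) tracks killing and hemolysis far faster than
overnight CFU plating.

## The model

A cell in suspension is described by the **single-shell model**: a
conductive cytoplasm sphere (radius *R*, complex permittivity
ε*<sub>cyt</sub>) covered by a thin, poorly conducting membrane
(thickness *d*, ε*<sub>mem</sub>), with ε* = ε₀ε<sub>r</sub> − jσ/ω.
The shell is reduced to an equivalent homogeneous permittivity

    ε*_eq = ε*_mem · (γ³ + 2Δ) / (γ³ − Δ),   γ = R/(R−d),
    Δ = (ε*_cyt − ε*_mem) / (ε*_cyt + 2 ε*_mem)

and the demodulated signal of one transit is a **bipolar Gaussian pulse**
with complex amplitude A<sub>f</sub> ∝ (2R)³ · f<sub>CM</sub>(f), where
f<sub>CM</sub> = (ε*<sub>p</sub> − ε*<sub>m</sub>)/(ε*<sub>p</sub> + 2ε*<sub>m</sub>)
is the Clausius–Mossotti contrast factor against the buffer. Each detected
event is fitted with the template A<sub>f</sub>·[g(t−t₁) − g(t−t₂)]
(timing shared across the 0.5/11/20 MHz channels), yielding per frequency the

* **electrical diameter** |A<sub>f</sub>|<sup>1/3</sup>, bead-calibrated to μm, and
* **phase** arg A<sub>f</sub>, bead-referenced to 0 rad,

using spiked-in 4.5 μm polystyrene beads as internal reference. Bacteria
and RBCs are gated at 3.8 μm electrical diameter (0.5 MHz); RBCs split
into healthy (**H**, high phase) and damaged (**L**, low phase)
subpopulations at 20 MHz. Dose–response readouts — % killing from CFU
counts, % hemolysis from absorbance, normalized median phase, normalized
L-fraction f<sub>L</sub> — are fitted with the **Hill model**

    y(x) = 100 · xⁿ / (Kⁿ + xⁿ)

where *K* is the half-effect peptide concentration (μM) and *n* the
cooperativity.

## Worked example

Run a full simulated assay — 6 peptide doses (0.025–0.80 μM) plus negative
and positive controls for both a bacterial and an RBC dose series and a
mixed bacteria+RBC sample — and fit all four dose–response curves:

```python
from ampcyt import RunConfig, run_pipeline, summarize

cfg = RunConfig(seed=1, duration_s=3.0, output_dir="demo_run")
run_pipeline(cfg)
print(summarize("demo_run"))
```

or equivalently from the shell: `ampcyt run-all -o demo_run --seed 1`.
The report ends with (output of the exact commands above):

```
Hill fits (K in uM):
        bacteria_cfu: K = 0.0271 +/- 0.000136, n = 2.28 +/- 0.0289
  bacteria_impedance: K = 0.0756 +/- 0.0151, n = 1.2 +/- 0.289
       rbc_hemolysis: K = 0.15 +/- 0.00102, n = 1.58 +/- 0.0155
       rbc_impedance: K = 0.154 +/- 0.00962, n = 1.33 +/- 0.106
```

Reading these numbers: the reference CFU killing curve recovers the
generator's kill parameters (K ≈ 0.03 μM, steep slope), while the
impedance phase readout of the same bacteria rises with a markedly
shallower slope (n ≈ 1.2 < 2.3) and half-point near 0.08 μM — the
signature of progressive peptide accumulation in dead cells, which keeps
shifting the high-frequency phase after killing is already complete. For
RBCs the impedance L-fraction curve and the reference hemolysis curve agree
closely (K ≈ 0.15 μM, n ≈ 1.3–1.6): counting damaged cells electrically
reproduces bulk hemoglobin release, with single-cell resolution. The
per-sample table above the fits lists event counts per stage (ground truth,
detected, retained) and per class (bead/bacterium/RBC-H/RBC-L), plus median
phases with interquartile ranges and f_L per sample.

The CLI also exposes the stages separately (`ampcyt simulate`, `process`,
`fit`, `report`) so streams and event tables can be re-analysed; every
stage re-run from the same config + seed is byte-identical.

## Layout

| module | role |
|---|---|
| `ampcyt.dielectric` | complex permittivity, single-shell model, Clausius–Mossotti factor |
| `ampcyt.synth` | acquisition config, pulse synthesis, stream + reference-assay generators |
| `ampcyt.events` | matched-filter detection, bipolar-Gaussian template fitting, features |
| `ampcyt.calibrate` | bead identification, diameter/phase calibration, gating, H/L split |
| `ampcyt.dose_response` | killing/hemolysis/normalized-phase/f_L transforms, Hill fits |
| `ampcyt.config` / `pipeline` / `cli` | YAML run configs, orchestration, `ampcyt` command |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
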