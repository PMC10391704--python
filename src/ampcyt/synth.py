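"""Synthetic impedance-cytometry data generator.

Emulates a three-electrode differential microfluidic impedance chip with
lock-in demodulation at three stimulation frequencies (0.5, 11 and 20 MHz by
default, sampled at 115 kHz).  Each particle transit produces a bipolar
Gaussian pulse in every frequency channel whose complex amplitude is

    A_f = gain * d^3 * f_CM(f),

i.e. proportional to particle volume times the Clausius-Mossotti contrast
factor of the particle's dielectric model against the suspending buffer.
Reference beads are insulating and non-dispersive, so their phase is (nearly)
frequency independent and serves as the instrument phase reference.

The generator also produces toy reference-assay tables (CFU counts for the
bactericidal assay, supernatant absorbances for the hemolysis assay) driven
by the same Hill-type dose model, so the impedance-derived dose-response
curves can be compared with reference curves on known ground truth.

Dielectric parameter defaults (:data:`BUFFER_A`, :data:`RBC_HEALTHY`, ...)
are literature-typical assumptions, not measured values; they are chosen to
reproduce the qualitative orderings observed experimentally (damaged RBCs
have lower high-frequency phase than healthy ones; dead bacteria have
high-frequency phase closer to the bead reference than live ones).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .dielectric import (
    Bead,
    Medium,
    ShellCell,
    clausius_mossotti,
    particle_permittivity,
)
from .exceptions import InvalidArgumentError

PopulationLabel = Literal["bead", "bacterium_live", "bacterium_dead", "rbc_H", "rbc_L"]

# ---------------------------------------------------------------------------
# Default dielectric parameters (assumptions; see docs/methods.md)
# ---------------------------------------------------------------------------

#: HEPES/KCl/glucose suspension buffer (~110 mM KCl).
BUFFER_A = Medium(conductivity=1.3, relative_permittivity=80.0)

#: 4.5 um polystyrene reference bead.
POLYSTYRENE_BEAD = Bead(diameter_um=4.5, conductivity=1e-6, rel_permittivity=2.55)

#: Healthy red blood cell (sphered), ~5.8 um electrical diameter at 0.5 MHz.
RBC_HEALTHY = ShellCell(
    radius_um=2.9,
    membrane_thickness_nm=5.0,
    membrane_conductivity=1e-6,
    membrane_rel_permittivity=5.6,
    cytoplasm_conductivity=0.52,
    cytoplasm_rel_permittivity=59.0,
)

#: Damaged ("ghost") RBC: porated membrane (conductivity up ~1e3x), cytoplasm
#: largely replaced by suspension medium (conductivity and permittivity up).
RBC_DAMAGED = ShellCell(
    radius_um=2.9,
    membrane_thickness_nm=5.0,
    membrane_conductivity=1e-3,
    membrane_rel_permittivity=5.6,
    cytoplasm_conductivity=1.15,
    cytoplasm_rel_permittivity=80.0,
)

#: Live Gram-positive bacterium (B. megaterium-like), ~3 um electrical
#: diameter at 0.5 MHz; the shell lumps membrane plus cell wall.
BACTERIUM_LIVE = ShellCell(
    radius_um=1.5,
    membrane_thickness_nm=15.0,
    membrane_conductivity=1e-6,
    membrane_rel_permittivity=8.0,
    cytoplasm_conductivity=0.9,
    cytoplasm_rel_permittivity=60.0,
)

#: Peptide-killed bacterium: permeabilized envelope and rigidified,
#: peptide-bound cytosol (strongly reduced interior conductivity), which
#: moves the high-frequency phase toward the bead reference.
BACTERIUM_DEAD = ShellCell(
    radius_um=1.5,
    membrane_thickness_nm=15.0,
    membrane_conductivity=1e-4,
    membrane_rel_permittivity=8.0,
    cytoplasm_conductivity=0.05,
    cytoplasm_rel_permittivity=50.0,
)


# ---------------------------------------------------------------------------
# Configuration dataclasses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionConfig:
    """Instrument geometry, electronics and disturbance model.

    ``gain`` converts particle volume (um^3) times the Clausius-Mossotti
    factor into demodulated signal units.  ``position_blur_rel_sd`` and
    ``position_phase_sd`` model position-induced blurring from the
    non-uniform electric field (multiplicative lognormal magnitude jitter and
    additive Gaussian phase jitter, one draw per event applied to every
    frequency channel).  The phase jitter default reproduces a bead-phase
    scatter of about 0.03 rad.
    """

    frequencies: tuple[float, ...] = (0.5e6, 11e6, 20e6)
    sampling_rate: float = 115e3
    electrode_width_um: float = 30.0
    electrode_gap_um: float = 10.0
    channel_width_um: float = 40.0
    channel_height_um: float = 20.0
    flow_rate_ul_min: float = 10.0
    noise_rms: float = 0.5
    position_blur_rel_sd: float = 0.15
    position_phase_sd: float = 0.03
    gain: float = 1.0
    velocity_rel_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise InvalidArgumentError("sampling_rate must be > 0")
        for name in (
            "electrode_width_um",
            "electrode_gap_um",
            "channel_width_um",
            "channel_height_um",
            "flow_rate_ul_min",
        ):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be > 0")
        freqs = tuple(self.frequencies)
        if len(freqs) != len(set(freqs)) or any(f <= 0 for f in freqs):
            raise InvalidArgumentError("frequencies must be distinct and positive")
        if self.noise_rms < 0 or self.position_blur_rel_sd < 0 or self.position_phase_sd < 0:
            raise InvalidArgumentError("noise/blur parameters must be >= 0")
        if self.gain <= 0:
            raise InvalidArgumentError("gain must be > 0")

    @property
    def mean_velocity(self) -> float:
        """Mean transit velocity (m/s) from flow rate over channel section."""
        q = self.flow_rate_ul_min * 1e-9 / 60.0  # m^3/s
        area = self.channel_width_um * self.channel_height_um * 1e-12  # m^2
        return q / area

    @property
    def lobe_separation_s(self) -> float:
        """Nominal bipolar lobe separation (centre-to-centre) in seconds."""
        return (self.electrode_width_um + self.electrode_gap_um) * 1e-6 / self.mean_velocity

    @property
    def lobe_sigma_s(self) -> float:
        """Nominal Gaussian lobe width in seconds."""
        return self.electrode_width_um * 1e-6 / (2.0 * self.mean_velocity)


@dataclass(frozen=True)
class PopulationSpec:
    """A particle population in the sample.

    ``damaged_model`` is the dielectric model an event from this population
    switches to when the dose model marks it as dead (bacteria) or lysed
    (RBC); it only applies to the ``bacterium_live`` and ``rbc_H`` labels.
    """

    label: PopulationLabel
    cell_model: ShellCell | Bead
    concentration_per_ml: float
    size_cv: float = 0.05
    damaged_model: ShellCell | None = None

    def __post_init__(self) -> None:
        if self.concentration_per_ml < 0:
            raise InvalidArgumentError("concentration must be >= 0")
        if self.size_cv < 0:
            raise InvalidArgumentError("size_cv must be >= 0")


@dataclass(frozen=True)
class DoseModel:
    """Hill-type dose dependence of the damaged fractions.

    ``k_kill_um``/``n_kill`` give the fraction of dead bacteria as a function
    of peptide concentration; ``k_lysis_um``/``n_lysis`` the fraction of
    damaged (L) RBCs.  ``accumulation_slope`` (rad-fraction per decade of
    dose) makes the electrical signature of dead bacteria keep drifting
    toward the fully-transformed state as dose grows beyond the kill
    half-point, emulating progressive peptide accumulation in the cytosol;
    0 disables the effect (dead cells jump straight to the dead model).
    """

    k_kill_um: float = 0.034
    n_kill: float = 2.7
    k_lysis_um: float = 0.15
    n_lysis: float = 1.5
    accumulation_slope: float = 0.25

    def __post_init__(self) -> None:
        if self.k_kill_um <= 0 or self.k_lysis_um <= 0:
            raise InvalidArgumentError("Hill K parameters must be > 0")
        if self.n_kill <= 0 or self.n_lysis <= 0:
            raise InvalidArgumentError("Hill n parameters must be > 0")
        if self.accumulation_slope < 0:
            raise InvalidArgumentError("accumulation_slope must be >= 0")


@dataclass
class StreamBundle:
    """Demodulated differential streams plus synthetic ground truth.

    ``data`` maps stimulation frequency (Hz) to the complex in-phase +
    j*quadrature sample sequence.  ``ground_truth`` has one row per generated
    event: arrival time, label, velocity, truncation flag and the realized
    (blurred) complex amplitude per frequency.
    """

    data: dict[float, np.ndarray]
    sampling_rate: float
    ground_truth: pd.DataFrame
    config: AcquisitionConfig

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(self.data.keys())

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.data.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def save(self, path: str | Path) -> None:
        """Write streams as an .npz container and ground truth as CSV."""
        path = Path(path)
        arrays = {f"stream_{f:.0f}": v for f, v in self.data.items()}
        np.savez_compressed(
            path.with_suffix(".npz"),
            sampling_rate=self.sampling_rate,
            frequencies=np.array(list(self.data.keys())),
            config=np.array([repr(self.config)]),
            **arrays,
        )
        self.ground_truth.to_csv(path.with_suffix(".truth.csv"), index=False)

    @classmethod
    def load(cls, path: str | Path, config: AcquisitionConfig | None = None) -> "StreamBundle":
        path = Path(path)
        with np.load(path.with_suffix(".npz"), allow_pickle=False) as npz:
            freqs = npz["frequencies"]
            data = {float(f): npz[f"stream_{f:.0f}"] for f in freqs}
            rate = float(npz["sampling_rate"])
        truth_path = path.with_suffix(".truth.csv")
        truth = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame()
        return cls(
            data=data,
            sampling_rate=rate,
            ground_truth=truth,
            config=config or AcquisitionConfig(sampling_rate=rate, frequencies=tuple(data)),
        )


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def freq_key(frequency: float) -> str:
    """Column-name key for a stimulation frequency, e.g. ``0.5MHz``."""
    return f"{frequency / 1e6:g}MHz"


def event_amplitude(
    particle: ShellCell | Bead | PopulationSpec,
    frequency: float,
    medium: Medium = BUFFER_A,
    gain: float = 1.0,
) -> complex:
    """Complex peak amplitude of one particle transit at one frequency.

    amplitude = gain * diameter^3 * f_CM(frequency); the cubic diameter
    scaling makes the cube root of the bead-calibrated amplitude recover the
    particle diameter at low frequency.
    """
    if isinstance(particle, PopulationSpec):
        particle = particle.cell_model
    eps_p = particle_permittivity(particle, frequency)
    fcm = clausius_mossotti(eps_p, medium.complex_permittivity(frequency))
    return gain * particle.diameter_um**3 * fcm


def dose_population_fractions(dose_um: float, model: DoseModel) -> tuple[float, float]:
    """(fraction of dead bacteria, fraction of L-type RBCs) at a dose.

    Each fraction follows the Hill law dose^n / (K^n + dose^n) with the
    respective (K, n); both lie in [0, 1] and equal 0.5 exactly at dose = K.
    """
    if dose_um < 0:
        raise InvalidArgumentError("dose must be >= 0")
    return (
        _hill_fraction(dose_um, model.k_kill_um, model.n_kill),
        _hill_fraction(dose_um, model.k_lysis_um, model.n_lysis),
    )


def _hill_fraction(x: float, k: float, n: float) -> float:
    if x == 0:
        return 0.0
    if np.isinf(x):
        return 1.0
    # log-space ratio form is overflow-safe for both tiny and huge doses
    log_r = n * (np.log(k) - np.log(x))
    if log_r > 700.0:
        return 0.0
    if log_r < -700.0:
        return 1.0
    return 1.0 / (1.0 + np.exp(log_r))


def accumulation_fraction(dose_um: float, model: DoseModel) -> float:
    """Interpolation weight s in [0, 1] between live and fully-dead signatures.

    With ``accumulation_slope`` = 0 a dead cell carries the fully-dead
    signature (s = 1).  Otherwise s = 0.5 at the kill half-point and grows by
    ``accumulation_slope`` per decade of dose, clipped to [0, 1].
    """
    if model.accumulation_slope == 0:
        return 1.0
    if dose_um <= 0:
        return 1.0
    s = 0.5 + model.accumulation_slope * np.log10(dose_um / model.k_kill_um)
    return float(np.clip(s, 0.0, 1.0))


def _interp_amplitude(a_live: complex, a_dead: complex, s: float) -> complex:
    """Geometric (log-domain) interpolation between two complex amplitudes."""
    return complex(np.exp((1.0 - s) * np.log(a_live) + s * np.log(a_dead)))


def bipolar_pulse(
    amplitude: complex,
    center_time: float,
    velocity: float,
    config: AcquisitionConfig,
    duration: float,
) -> np.ndarray:
    """Sampled bipolar Gaussian waveform of one transit.

    A * [g(t - t1) - g(t - t2)] with unit-peak Gaussian lobes g; the lobe
    separation t2 - t1 equals (electrode width + gap) / velocity and the lobe
    width is sigma = electrode width / (2 * velocity).
    """
    if velocity <= 0:
        raise InvalidArgumentError("velocity must be > 0")
    n = int(round(duration * config.sampling_rate))
    out = np.zeros(n, dtype=complex)
    _add_pulse(out, amplitude, center_time, velocity, config)
    return out


def pulse_is_truncated(
    center_time: float, velocity: float, config: AcquisitionConfig, duration: float
) -> bool:
    sep = (config.electrode_width_um + config.electrode_gap_um) * 1e-6 / velocity
    sigma = config.electrode_width_um * 1e-6 / (2.0 * velocity)
    return center_time - sep / 2 - 3 * sigma < 0 or center_time + sep / 2 + 3 * sigma > duration


def _add_pulse(
    stream: np.ndarray,
    amplitude: complex,
    center_time: float,
    velocity: float,
    config: AcquisitionConfig,
) -> None:
    """Add one bipolar pulse to ``stream`` in place (local slice only)."""
    fs = config.sampling_rate
    sep = (config.electrode_width_um + config.electrode_gap_um) * 1e-6 / velocity
    sigma = config.electrode_width_um * 1e-6 / (2.0 * velocity)
    t1 = center_time - sep / 2.0
    t2 = center_time + sep / 2.0
    lo = max(0, int(np.floor((t1 - 5 * sigma) * fs)))
    hi = min(len(stream), int(np.ceil((t2 + 5 * sigma) * fs)) + 1)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / fs
    b = np.exp(-0.5 * ((t - t1) / sigma) ** 2) - np.exp(-0.5 * ((t - t2) / sigma) ** 2)
    stream[lo:hi] += amplitude * b


# ---------------------------------------------------------------------------
# Stream generation
# ---------------------------------------------------------------------------


def _scaled_particle(model: ShellCell | Bead, factor: float) -> ShellCell | Bead:
    if isinstance(model, Bead):
        return dataclasses.replace(model, diameter_um=model.diameter_um * factor)
    return dataclasses.replace(model, radius_um=model.radius_um * factor)


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean lognormal multipliers with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=size)


def generate_stream(
    populations: Sequence[PopulationSpec],
    dose_um: float,
    dose_model: DoseModel,
    config: AcquisitionConfig,
    duration: float,
    seed: int,
    medium: Medium = BUFFER_A,
) -> StreamBundle:
    """Simulate demodulated differential streams for one sample.

    Events arrive as a Poisson process with rate concentration x flow rate
    (summed over populations); per-event size is lognormal around the
    population nominal; live bacteria / healthy RBCs flip to their damaged
    state with the dose-dependent Hill fractions; each event's amplitude is
    perturbed by position-induced magnitude and phase jitter; additive white
    Gaussian noise of ``config.noise_rms`` is applied per quadrature on each
    frequency channel.  The same seed reproduces the bundle bit-for-bit.
    """
    if not populations:
        raise InvalidArgumentError("population list must not be empty")
    if duration <= 0:
        raise InvalidArgumentError("duration must be > 0")
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate
    n = int(round(duration * fs))
    freqs = tuple(config.frequencies)
    streams = {f: np.zeros(n, dtype=complex) for f in freqs}
    f_dead, f_lysed = dose_population_fractions(dose_um, dose_model)
    s_acc = accumulation_fraction(dose_um, dose_model)

    rows: list[dict] = []
    for pop in populations:
        rate = pop.concentration_per_ml * config.flow_rate_ul_min * 1e-3 / 60.0  # events/s
        n_ev = rng.poisson(rate * duration)
        if n_ev == 0:
            continue
        times = rng.uniform(0.0, duration, n_ev)
        size_factors = _lognormal_factor(rng, pop.size_cv, n_ev)
        velocities = config.mean_velocity * _lognormal_factor(rng, config.velocity_rel_sd, n_ev)
        mag_jitter = _lognormal_factor(rng, config.position_blur_rel_sd, n_ev)
        phase_jitter = rng.normal(0.0, config.position_phase_sd, n_ev)
        if pop.label == "bacterium_live" and pop.damaged_model is not None:
            damaged = rng.random(n_ev) < f_dead
            damaged_label = "bacterium_dead"
        elif pop.label == "rbc_H" and pop.damaged_model is not None:
            damaged = rng.random(n_ev) < f_lysed
            damaged_label = "rbc_L"
        else:
            damaged = np.zeros(n_ev, dtype=bool)
            damaged_label = pop.label

        # progressive peptide accumulation is a bacterial cytosol mechanism;
        # a lysed RBC carries the full damaged signature from the start
        s_pop = s_acc if damaged_label == "bacterium_dead" else 1.0
        for i in range(n_ev):
            live_model = _scaled_particle(pop.cell_model, size_factors[i])
            blur = mag_jitter[i] * np.exp(1j * phase_jitter[i])
            amps: dict[float, complex] = {}
            for f in freqs:
                a = event_amplitude(live_model, f, medium, config.gain)
                if damaged[i]:
                    dead_model = _scaled_particle(pop.damaged_model, size_factors[i])
                    a_dead = event_amplitude(dead_model, f, medium, config.gain)
                    a = _interp_amplitude(a, a_dead, s_pop)
                amps[f] = a * blur
            label = damaged_label if damaged[i] else pop.label
            truncated = pulse_is_truncated(times[i], velocities[i], config, duration)
            row = {
                "arrival_time": times[i],
                "label": label,
                "velocity": velocities[i],
                "truncated": truncated,
            }
            for f in freqs:
                row[f"amp_re_{freq_key(f)}"] = amps[f].real
                row[f"amp_im_{freq_key(f)}"] = amps[f].imag
                _add_pulse(streams[f], amps[f], times[i], velocities[i], config)
            rows.append(row)

    if config.noise_rms > 0:
        for f in freqs:
            streams[f] += rng.normal(0.0, config.noise_rms, n) + 1j * rng.normal(
                0.0, config.noise_rms, n
            )

    columns = ["arrival_time", "label", "velocity", "truncated"] + [
        f"amp_{p}_{freq_key(f)}" for f in freqs for p in ("re", "im")
    ]
    truth = pd.DataFrame(rows, columns=columns)
    if len(truth):
        truth = truth.sort_values("arrival_time", ignore_index=True)
    return StreamBundle(data=streams, sampling_rate=fs, ground_truth=truth, config=config)


def default_populations(
    include_beads: bool = True,
    include_bacteria: bool = True,
    include_rbc: bool = True,
    bead_concentration: float = 2e5,
    bacteria_concentration: float = 4e5,
    rbc_concentration: float = 3e5,
) -> list[PopulationSpec]:
    """Populations at the nominal assay concentrations (particles per mL).

    Defaults: 2e5 beads, 4e5 bacteria (CFU) and 3e5 RBCs per mL, which at a
    10 uL/min flow rate yields an event rate of about 150 per second.
    """
    pops: list[PopulationSpec] = []
    if include_beads:
        pops.append(
            PopulationSpec("bead", POLYSTYRENE_BEAD, bead_concentration, size_cv=0.015)
        )
    if include_bacteria:
        pops.append(
            PopulationSpec(
                "bacterium_live",
                BACTERIUM_LIVE,
                bacteria_concentration,
                size_cv=0.06,
                damaged_model=BACTERIUM_DEAD,
            )
        )
    if include_rbc:
        pops.append(
            PopulationSpec(
                "rbc_H", RBC_HEALTHY, rbc_concentration, size_cv=0.10, damaged_model=RBC_DAMAGED
            )
        )
    return pops


#: Peptide concentration grid used for the dose series (uM).
DEFAULT_DOSE_GRID = (0.025, 0.05, 0.10, 0.20, 0.40, 0.80)

#: Saturating peptide concentration used as bacterial positive control (uM).
PC_DOSE_BACTERIA = 2.0


def generate_reference_assays(
    dose_grid: Sequence[float],
    dose_model: DoseModel,
    cfu_nc: int,
    seed: int,
    abs_nc: float = 0.05,
    abs_pc: float = 1.00,
    abs_noise_sd: float = 0.01,
    pc_dose_um: float = PC_DOSE_BACTERIA,
) -> pd.DataFrame:
    """Toy reference-assay table: CFU counts and hemolysis absorbances.

    Per dose the plated CFU count is Poisson with mean cfu_nc x survival and
    the supernatant absorbance interpolates between the negative-control and
    positive-control levels according to the lysed fraction, plus Gaussian
    noise.  Rows with role 'NC' (dose 0) and 'PC' (saturating peptide for
    bacteria; osmotic shock, i.e. complete lysis, for the absorbance) are
    included.
    """
    if cfu_nc <= 0:
        raise InvalidArgumentError("cfu_nc must be > 0")
    rng = np.random.default_rng(seed)
    rows = []

    def make_row(role: str, dose: float, survival: float, lysed: float) -> dict:
        cfu = int(rng.poisson(cfu_nc * survival))
        absorbance = abs_nc + (abs_pc - abs_nc) * lysed + rng.normal(0.0, abs_noise_sd)
        return {"role": role, "dose_um": dose, "cfu": cfu, "absorbance": absorbance}

    rows.append(make_row("NC", 0.0, 1.0, 0.0))
    for dose in dose_grid:
        f_dead, f_lysed = dose_population_fractions(float(dose), dose_model)
        rows.append(make_row("dose", float(dose), 1.0 - f_dead, f_lysed))
    f_dead_pc, _ = dose_population_fractions(pc_dose_um, dose_model)
    pc = make_row("PC", pc_dose_um, 1.0 - f_dead_pc, 1.0)
    rows.append(pc)
    return pd.DataFrame(rows)
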