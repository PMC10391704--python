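"""Dose-response metrics and Hill-model fitting.

Four response transforms map raw readouts onto a common 0-100 % axis using
negative-control (NC, untreated) and positive-control (PC, complete effect)
anchors:

* killing %          = (1 - CFU/CFU_NC) * 100
* hemolysis %        = (Abs - Abs_NC) / (Abs_PC - Abs_NC) * 100
* normalized phase % = (Ph - Ph_NC) / (Ph_PC - Ph_NC) * 100     (Ph = median)
* normalized f_L %   = (f_L - f_L,NC) / (f_L,PC - f_L,NC) * 100

The Hill model y(x) = 100 * x^n / (K^n + x^n) is fit to each curve by
unweighted nonlinear least squares; K is the half-effect concentration and n
the cooperativity (slope) parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from lmfit import Model

from .calibrate import GateConfig, split_HL, _circular_median
from .exceptions import DegenerateInputError, InvalidArgumentError
from .synth import freq_key

ResponseType = Literal["killing", "hemolysis", "normalized_phase", "normalized_L_fraction"]


@dataclass
class DoseCurve:
    """A dose-response curve on the common percentage axis.

    ``x`` are peptide concentrations in uM (NC included at x = 0; a PC at a
    finite dose is included as a datapoint, an off-scale PC such as osmotic
    shock is used only as a normalization anchor).
    """

    x: np.ndarray
    y: np.ndarray
    response_type: ResponseType
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise InvalidArgumentError("x and y must have the same shape")
        if np.any(self.x < 0):
            raise InvalidArgumentError("doses must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"dose_um": self.x, "response_pct": self.y})
        df["response_type"] = self.response_type
        if self.counts is not None:
            df["n_events"] = self.counts
        return df


@dataclass(frozen=True)
class HillFit:
    """Result of fitting the Hill model to a dose curve."""

    K: float
    n: float
    K_stderr: float | None
    n_stderr: float | None
    rss: float
    converged: bool

    def to_dict(self) -> dict:
        return {
            "K_um": self.K,
            "n": self.n,
            "K_stderr": self.K_stderr,
            "n_stderr": self.n_stderr,
            "rss": self.rss,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# Response transforms
# ---------------------------------------------------------------------------


def killing_percent(cfu: float, cfu_nc: float) -> float:
    """Percent bacterial killing from plated CFU counts, (1 - S) * 100."""
    if cfu_nc <= 0:
        raise InvalidArgumentError("cfu_nc must be > 0")
    if cfu < 0:
        raise InvalidArgumentError("cfu must be >= 0")
    return (1.0 - cfu / cfu_nc) * 100.0


def hemolysis_percent(abs_value: float, abs_nc: float, abs_pc: float) -> float:
    """Percent hemoglobin release from supernatant absorbances."""
    if abs_pc == abs_nc:
        raise DegenerateInputError("PC and NC absorbances coincide")
    return (abs_value - abs_nc) / (abs_pc - abs_nc) * 100.0


def normalized_phase(ph: float, ph_nc: float, ph_pc: float) -> float:
    """Median-phase readout normalized between the NC and PC medians."""
    if ph_pc == ph_nc:
        raise DegenerateInputError("PC and NC phases coincide")
    return (ph - ph_nc) / (ph_pc - ph_nc) * 100.0


def normalized_L_fraction(f_l: float, f_l_nc: float, f_l_pc: float) -> float:
    """L-subpopulation fraction normalized between the NC and PC fractions."""
    if f_l_pc == f_l_nc:
        raise DegenerateInputError("PC and NC L-fractions coincide")
    return (f_l - f_l_nc) / (f_l_pc - f_l_nc) * 100.0


# ---------------------------------------------------------------------------
# Hill model
# ---------------------------------------------------------------------------


def hill_eval(x, K, n):
    """Hill dose-response, percent: 100 * x^n / (K^n + x^n)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    with np.errstate(over="ignore"):  # (K/x)^n -> inf is a valid 0% response
        r = (K / x[pos]) ** n
    out[pos] = 100.0 / (1.0 + r)
    return out if out.ndim else float(out)


def hill_fit(curve: "DoseCurve | tuple[np.ndarray, np.ndarray]") -> HillFit:
    """Fit (K, n) of the Hill model to a dose curve.

    Unweighted nonlinear least squares with deterministic initialization:
    K0 is the positive dose whose response is nearest 50 %, n0 = 1.
    Standard errors come from the fit covariance.  At least three distinct
    positive doses are required.  x = 0 points are retained (the model is
    exactly 0 there).
    """
    if isinstance(curve, DoseCurve):
        x, y = curve.x, curve.y
    else:
        x, y = (np.asarray(v, dtype=float) for v in curve)
    pos = x > 0
    if len(np.unique(x[pos])) < 3:
        raise InvalidArgumentError("need at least 3 distinct positive doses")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]

    k0 = float(x[x > 0][np.argmin(np.abs(y[x > 0] - 50.0))])
    model = Model(hill_eval)
    params = model.make_params(K=k0, n=1.0)
    params["K"].set(min=1e-12)
    params["n"].set(min=1e-6, max=50.0)
    result = model.fit(y, params, x=x)
    kerr = result.params["K"].stderr
    nerr = result.params["n"].stderr
    return HillFit(
        K=float(result.params["K"].value),
        n=float(result.params["n"].value),
        K_stderr=None if kerr is None else float(kerr),
        n_stderr=None if nerr is None else float(nerr),
        rss=float(np.sum(result.residual**2)),
        converged=bool(result.success),
    )


# ---------------------------------------------------------------------------
# Impedance-derived curves
# ---------------------------------------------------------------------------


def build_impedance_killing_curve(
    feature_tables: Mapping[float, pd.DataFrame],
    response: ResponseType = "normalized_phase",
    frequency: float = 20e6,
    nc_dose: float = 0.0,
    pc_dose: float | None = None,
    gate: GateConfig | None = None,
) -> DoseCurve:
    """Impedance dose-response curve from per-dose gated feature tables.

    Parameters
    ----------
    feature_tables : mapping dose (uM) -> calibrated, gated feature table
        Must contain the NC (``nc_dose``) and the PC sample.  For the RBC
        readout an osmotic-shock PC has no meaningful dose; use
        ``float('inf')`` as its key.
    response : ``normalized_phase`` (bacteria) or ``normalized_L_fraction``
        (RBC).
    frequency : float
        Stimulation frequency of the phase readout (default 20 MHz).
    pc_dose : float, optional
        Key of the PC sample; defaults to the largest dose present.

    For bacteria the per-dose statistic is the median phase of
    bacterium-labelled events; for RBCs it is f_L from the H/L split.  The
    statistic is normalized between its NC and PC values; a finite-dose PC is
    kept as a datapoint (at 100 %), an infinite-dose PC is excluded from the
    returned curve.
    """
    if nc_dose not in feature_tables:
        raise InvalidArgumentError("NC sample (dose = nc_dose) is missing")
    doses = sorted(feature_tables)
    if pc_dose is None:
        pc_dose = doses[-1]
    if pc_dose not in feature_tables or pc_dose == nc_dose:
        raise InvalidArgumentError("PC sample is missing or coincides with NC")

    if response == "normalized_phase":
        stats = {d: _median_bacteria_phase(t, frequency) for d, t in feature_tables.items()}
        transform = normalized_phase
    elif response == "normalized_L_fraction":
        gate = gate or _fl_gate_from_anchors(
            feature_tables[nc_dose], feature_tables[pc_dose], frequency
        )
        stats = {d: split_HL(_rbc_subset(t), gate)[1] for d, t in feature_tables.items()}
        transform = normalized_L_fraction
    else:
        raise InvalidArgumentError(f"unsupported impedance response: {response}")

    nc_stat, pc_stat = stats[nc_dose], stats[pc_dose]
    xs, ys, ns = [], [], []
    for d in doses:
        if np.isinf(d):
            continue
        xs.append(d)
        ys.append(transform(stats[d], nc_stat, pc_stat))
        ns.append(len(feature_tables[d]))
    return DoseCurve(
        x=np.array(xs), y=np.array(ys), response_type=response, counts=np.array(ns)
    )


def _rbc_subset(features: pd.DataFrame) -> pd.DataFrame:
    sub = features[features["class_label"].astype(str).str.startswith("rbc")]
    if len(sub) == 0:
        raise InvalidArgumentError("no RBC-labelled events in feature table")
    return sub


def _median_bacteria_phase(features: pd.DataFrame, frequency: float) -> float:
    sub = features[features["class_label"] == "bacterium"]
    if len(sub) == 0:
        raise InvalidArgumentError("no bacterium-labelled events in feature table")
    return float(sub[f"phase_{freq_key(frequency)}"].median())


def _fl_gate_from_anchors(
    nc_table: pd.DataFrame, pc_table: pd.DataFrame, frequency: float
) -> GateConfig:
    """Fixed H/L phase threshold at the midpoint of the NC and PC medians.

    For a dose series the NC sample is (almost) all healthy and the PC sample
    all damaged, so the midpoint of their median phases is a robust split
    point even for samples where one subpopulation is nearly absent (where a
    blind mixture fit would be degenerate).
    """
    key = f"phase_{freq_key(frequency)}"
    ph_nc = _circular_median(_rbc_subset(nc_table)[key].to_numpy(dtype=float))
    ph_pc = _circular_median(_rbc_subset(pc_table)[key].to_numpy(dtype=float))
    return GateConfig(
        hl_split_frequency=frequency,
        hl_method="fixed_threshold",
        hl_fixed_threshold=0.5 * (ph_nc + ph_pc),
    )


def reference_killing_curve(assays: pd.DataFrame) -> DoseCurve:
    """Killing-% curve from a reference CFU assay table."""
    nc = assays.loc[assays["role"] == "NC"]
    if len(nc) != 1:
        raise InvalidArgumentError("assay table must contain exactly one NC row")
    cfu_nc = float(nc["cfu"].iloc[0])
    y = np.array([killing_percent(c, cfu_nc) for c in assays["cfu"]])
    return DoseCurve(
        x=assays["dose_um"].to_numpy(dtype=float), y=y, response_type="killing"
    )


def reference_hemolysis_curve(assays: pd.DataFrame) -> DoseCurve:
    """Hemolysis-% curve from a reference absorbance assay table.

    The PC row (complete lysis) anchors 100 % and is excluded from the
    returned curve (its nominal dose refers to the bacterial PC, not to a
    hemolytic dose).
    """
    nc = assays.loc[assays["role"] == "NC"]
    pc = assays.loc[assays["role"] == "PC"]
    if len(nc) != 1 or len(pc) != 1:
        raise InvalidArgumentError("assay table must contain exactly one NC and one PC row")
    abs_nc = float(nc["absorbance"].iloc[0])
    abs_pc = float(pc["absorbance"].iloc[0])
    rows = assays.loc[assays["role"].isin(["NC", "dose"])]
    y = np.array([hemolysis_percent(a, abs_nc, abs_pc) for a in rows["absorbance"]])
    return DoseCurve(x=rows["dose_um"].to_numpy(dtype=float), y=y, response_type="hemolysis")
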