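"""Gating current–voltage models and the single-barrier conductance analysis.

Three descriptive models:

* the two-state Boltzmann sigmoid P_o(V) = 1/(1 + exp(−q e (V − V½)/kB T)),
  fitted by nonlinear least squares to (voltage, open-probability) data to
  give the apparent gating charge q.  The single-step assumption behind it
  is almost certainly wrong for real channels, so the fit is descriptive;
* a Gaussian-threshold alternative, in which opening occurs when the
  voltage-coupled energy drive q·e·V/kBT crosses a threshold distributed
  normally with width about one kBT — giving a probit curve that is nearly
  indistinguishable from the Boltzmann once midpoints are aligned and the
  width chosen to minimize the sup deviation (the familiar ≈1.702 probit/
  logit scale factor emerges from that match);
* the single-barrier conductance picture, in which relative conductance is
  linear in ln[K+], i.e. in the free energy −RT ln(c/c_ref) of the ion in
  solution; log-log linearity (R² ≈ 1) is the diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from protongate.thermal_kinetics import CONSTANTS, ROOM_TEMPERATURE_K

__all__ = [
    "GatingDataset",
    "BoltzmannFit",
    "ThresholdModel",
    "ConductanceDataset",
    "BarrierFit",
    "NonIdentifiableError",
    "boltzmann_po",
    "fit_boltzmann",
    "threshold_po",
    "matched_threshold_model",
    "threshold_vs_boltzmann_deviation",
    "free_energy_shift",
    "barrier_linearity",
]


class NonIdentifiableError(ValueError):
    """The data cannot constrain the fit (e.g., all probabilities equal)."""


def _volts_per_kbt(t: float) -> float:
    """kB·T/e in volts at temperature t (≈25.85 mV at 300 K)."""
    return CONSTANTS.k_B * t / CONSTANTS.e


def boltzmann_po(
    v_mv: float | np.ndarray,
    q: float,
    v_half: float = 0.0,
    t: float = ROOM_TEMPERATURE_K,
) -> float | np.ndarray:
    """Open probability 1/(1 + exp(−q·e·(V − V½)/kB·T)).

    ``v_mv`` and ``v_half`` in mV, ``q`` in elementary charges.  With
    ``v_half = 0`` this is the textbook single-Boltzmann form.  Saturates
    smoothly (no overflow) at extreme voltages.
    """
    if t <= 0:
        raise ValueError(f"temperature must be > 0, got {t}")
    x = q * (np.asarray(v_mv, dtype=float) - v_half) * 1e-3 / _volts_per_kbt(t)
    out = special.expit(x)
    return float(out) if np.isscalar(v_mv) else out


@dataclass(frozen=True)
class GatingDataset:
    """(voltage mV, open probability) observations at one temperature."""

    voltages_mv: tuple[float, ...]
    open_probabilities: tuple[float, ...]
    temperature: float = ROOM_TEMPERATURE_K

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages_mv, dtype=float)
        p = np.asarray(self.open_probabilities, dtype=float)
        if v.shape != p.shape:
            raise ValueError("voltage and probability lengths differ")
        if not np.all(np.isfinite(v)):
            raise ValueError("voltages must be finite")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if len(np.unique(v)) < 2:
            raise ValueError("need at least 2 distinct voltages")

    @classmethod
    def from_csv(cls, path: str | Path, temperature: float = ROOM_TEMPERATURE_K) -> "GatingDataset":
        df = pd.read_csv(path)
        return cls(tuple(df.iloc[:, 0]), tuple(df.iloc[:, 1]), temperature)

    @property
    def v(self) -> np.ndarray:
        return np.asarray(self.voltages_mv, dtype=float)

    @property
    def p(self) -> np.ndarray:
        return np.asarray(self.open_probabilities, dtype=float)


@dataclass(frozen=True)
class BoltzmannFit:
    """Least-squares Boltzmann fit: gating charge, midpoint, uncertainties."""

    q: float
    v_half: float
    covariance: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    temperature: float = ROOM_TEMPERATURE_K

    @property
    def q_se(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    @property
    def v_half_se(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))

    @property
    def midpoint_slope(self) -> float:
        """dP_o/dV at the midpoint, per mV: q·e/(4·kB·T)·10⁻³ — the 'slope'
        of the gating curve, proportional to q."""
        return self.q * 1e-3 / (4.0 * _volts_per_kbt(self.temperature))

    def predict(self, v_mv: np.ndarray) -> np.ndarray:
        return boltzmann_po(v_mv, self.q, self.v_half, self.temperature)


def fit_boltzmann(data: GatingDataset) -> BoltzmannFit:
    """Fit (q, V½) by nonlinear least squares on the probabilities.

    Fitting on probabilities (not logits) keeps saturated points at 0/1
    usable.  Initialization: V½ from the interpolated 0.5 crossing, q from
    a central finite-difference slope.  Degenerate data (all probabilities
    equal) raise :class:`NonIdentifiableError`.
    """
    v, p = data.v, data.p
    if np.allclose(p, p[0]):
        raise NonIdentifiableError("all open probabilities equal; q not identifiable")
    order = np.argsort(v)
    vs, ps = v[order], p[order]
    # initial midpoint: interpolated 0.5 crossing (fall back to mid-range)
    try:
        v_half0 = float(np.interp(0.5, ps, vs)) if ps[0] < ps[-1] else float(
            np.interp(0.5, ps[::-1], vs[::-1])
        )
    except Exception:  # pragma: no cover - interp is forgiving
        v_half0 = float(vs.mean())
    # initial q from the steepest central finite-difference slope
    dp = np.gradient(ps, vs)
    slope0 = float(dp[np.argmax(np.abs(dp))])
    q0 = slope0 * 4.0 * _volts_per_kbt(data.temperature) * 1e3
    if not np.isfinite(q0) or q0 == 0.0:
        q0 = 1.0

    def model(vv, q, v_half):
        return boltzmann_po(vv, q, v_half, data.temperature)

    popt, _ = optimize.curve_fit(model, v, p, p0=[q0, v_half0], maxfev=20000)
    q_hat, v_half_hat = float(popt[0]), float(popt[1])
    fitted = model(v, q_hat, v_half_hat)
    residuals = p - fitted

    # HC3 sandwich covariance: probabilities recorded near 0/1 have their
    # noise truncated, so the error variance depends on voltage and the
    # homoscedastic curve_fit covariance understates the uncertainty in q.
    k = 1e-3 / _volts_per_kbt(data.temperature)
    w = fitted * (1.0 - fitted)
    jac = np.column_stack([w * k * (v - v_half_hat), -w * k * q_hat])
    jtj_inv = np.linalg.pinv(jac.T @ jac)
    leverage = np.einsum("ij,jk,ik->i", jac, jtj_inv, jac)
    omega = residuals**2 / np.clip(1.0 - leverage, 1e-8, None) ** 2
    pcov = jtj_inv @ (jac.T * omega) @ jac @ jtj_inv

    return BoltzmannFit(
        q=q_hat,
        v_half=v_half_hat,
        covariance=np.asarray(pcov),
        residuals=residuals,
        temperature=data.temperature,
    )


@dataclass(frozen=True)
class ThresholdModel:
    """Gaussian-threshold gating: opening when the voltage-coupled energy
    drive q·e·V/kBT crosses a normally distributed threshold.

    ``mean_threshold`` and ``width`` are in kBT units (width defaults to 1,
    the physically motivated scale); ``q`` couples voltage to energy.
    """

    mean_threshold: float
    width: float = 1.0
    q: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"width must be > 0, got {self.width}")


def threshold_po(
    v_mv: float | np.ndarray, m: ThresholdModel, t: float = ROOM_TEMPERATURE_K
) -> float | np.ndarray:
    """Φ((q·e·V/kBT − mean_threshold)/width): probit open probability."""
    drive = m.q * np.asarray(v_mv, dtype=float) * 1e-3 / _volts_per_kbt(t)
    out = special.ndtr((drive - m.mean_threshold) / m.width)
    return float(out) if np.isscalar(v_mv) else out


def matched_threshold_model(
    q: float,
    v_half: float = 0.0,
    t: float = ROOM_TEMPERATURE_K,
    match: str = "minimax",
) -> ThresholdModel:
    """Threshold model matched to a Boltzmann (q, V½) curve.

    The midpoint is matched exactly (mean threshold = drive at V½).  The
    width is chosen either to minimize the sup |probit − logistic|
    deviation (``match="minimax"``, the default — the ≈1.702 probit/logit
    factor emerges) or to equate midpoint slopes (``match="slope"``, width
    4/√(2π) ≈ 1.596, which leaves a larger sup deviation ≈ 0.018).
    """
    mean = q * v_half * 1e-3 / _volts_per_kbt(t)
    if match == "slope":
        width = 4.0 / np.sqrt(2.0 * np.pi)
    elif match == "minimax":
        x = np.linspace(-12.0, 12.0, 4001)
        logistic = special.expit(x)

        def sup_dev(w):
            return np.max(np.abs(special.ndtr(x / w) - logistic))

        width = float(optimize.minimize_scalar(sup_dev, bounds=(1.2, 2.2), method="bounded").x)
    else:
        raise ValueError(f"match must be 'minimax' or 'slope', got {match!r}")
    return ThresholdModel(mean_threshold=mean, width=width, q=q)


def threshold_vs_boltzmann_deviation(
    m: ThresholdModel,
    q: float,
    v_half: float = 0.0,
    t: float = ROOM_TEMPERATURE_K,
    v_grid: Sequence[float] | np.ndarray | None = None,
) -> float:
    """Sup over the grid of |threshold_po − boltzmann_po|.

    ``v_grid`` must span both transitions; default is a dense grid covering
    ±20 transition widths around V½.  Empty grid raises ValueError.
    """
    if v_grid is None:
        scale_mv = _volts_per_kbt(t) * 1e3 / abs(q) if q else 100.0
        v_grid = np.linspace(v_half - 20 * scale_mv, v_half + 20 * scale_mv, 20001)
    v_grid = np.asarray(v_grid, dtype=float)
    if v_grid.size == 0:
        raise ValueError("empty voltage grid")
    diff = threshold_po(v_grid, m, t) - boltzmann_po(v_grid, q, v_half, t)
    return float(np.max(np.abs(diff)))


@dataclass(frozen=True)
class ConductanceDataset:
    """(concentration mM, relative conductance) points for barrier analysis."""

    concentrations_mm: tuple[float, ...]
    conductances: tuple[float, ...]
    temperature: float = ROOM_TEMPERATURE_K
    reference_concentration_mm: float = 1.0

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_mm, dtype=float)
        g = np.asarray(self.conductances, dtype=float)
        if c.shape != g.shape:
            raise ValueError("concentration and conductance lengths differ")
        if np.any(c <= 0):
            raise ValueError("concentrations must be > 0")
        if self.reference_concentration_mm <= 0:
            raise ValueError("reference concentration must be > 0")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        temperature: float = ROOM_TEMPERATURE_K,
        reference_concentration_mm: float | None = None,
    ) -> "ConductanceDataset":
        df = pd.read_csv(path)
        c = tuple(df.iloc[:, 0])
        ref = reference_concentration_mm if reference_concentration_mm is not None else min(c)
        return cls(c, tuple(df.iloc[:, 1]), temperature, ref)


def free_energy_shift(c_mm: float, data: ConductanceDataset) -> float:
    """ΔΔG = −R·T·ln(c/c_ref) in kJ/mol, relative to the reference (low)
    concentration — the free energy of the ion in solution."""
    if c_mm <= 0:
        raise ValueError(f"concentration must be > 0, got {c_mm}")
    return float(
        -CONSTANTS.R
        * data.temperature
        * np.log(c_mm / data.reference_concentration_mm)
        / 1e3
    )


@dataclass(frozen=True)
class BarrierFit:
    """OLS of ln(conductance) on ln(concentration): linearity diagnostic."""

    slope: float
    intercept: float
    r_squared: float
    slope_se: float


def barrier_linearity(data: ConductanceDataset) -> BarrierFit:
    """Fit ln(g) = slope·ln(c) + b; R² near 1 is consistent with a single
    conduction barrier whose occupancy tracks the solution free energy."""
    c = np.asarray(data.concentrations_mm, dtype=float)
    g = np.asarray(data.conductances, dtype=float)
    if len(c) < 3:
        raise ValueError(f"need >= 3 points, got {len(c)}")
    if np.any(g <= 0):
        raise ValueError("conductances must be > 0 for log-log analysis")
    if np.allclose(np.log(g), np.log(g)[0]):
        # flat data: slope 0 by construction, R^2 undefined -> report 1 fit of a constant
        return BarrierFit(slope=0.0, intercept=float(np.log(g[0])), r_squared=1.0, slope_se=0.0)
    res = stats.linregress(np.log(c), np.log(g))
    return BarrierFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_se=float(res.stderr),
    )
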