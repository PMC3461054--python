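"""Two-state thermal unfolding analysis with Gibbs-Helmholtz stability curves.

A melting curve records the mean residue molar ellipticity of a protein
(usually at 222 nm, where the helix signal is strongest) as temperature is
ramped. Under an apparent two-state equilibrium N <-> U with linear native
and unfolded baselines, the observed signal is

    Y0(T) = (1 - fU) * (yN + mN*T) + fU * (yU + mU*T)

where fU is the unfolded fraction. From fU one obtains the apparent
equilibrium constant K = fU/(1-fU) and the unfolding free energy
dG = -R*T*ln K, and the stability curve dG(T) is fitted to the
Gibbs-Helmholtz equation

    dG(T) = dHm*(1 - T/Tm) + dCp*[(T - Tm) - T*ln(T/Tm)]

with Tm the transition midpoint, dHm the van't Hoff enthalpy at Tm and dCp
the heat-capacity change of unfolding. The stationary point of the curve,
Ts = Tm*exp(-dHm/(dCp*Tm)), is the temperature of maximum stability.

The fitting interface follows the model/results idiom: build a
:class:`TwoStateMeltModel` from data, call :meth:`~TwoStateMeltModel.fit`,
and read estimates, uncertainties and diagnostics off the returned
:class:`MeltResults`.
"""

from __future__ import annotations

import io as _io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "GAS_CONSTANT_KJ",
    "MeltCurve",
    "BaselineModel",
    "StabilityCurve",
    "ThermoParams",
    "TwoStateMeltModel",
    "MeltResults",
    "gibbs_helmholtz",
    "stationary_temperature",
    "dcp_from_stationarity",
    "delta_g_at",
    "fit_baselines",
    "unfolded_fraction",
    "free_energy_series",
    "fit_gibbs_helmholtz",
    "analyze_melt",
]

#: Gas constant in kJ mol^-1 K^-1.
GAS_CONSTANT_KJ = 8.314e-3

DEFAULT_TRANSITION_WINDOW = (288.0, 334.0)
DEFAULT_TREF = 295.0
FRACTION_CLIP_EPS = 1e-4


class MeltAnalysisError(ValueError):
    """Raised when a melt-analysis stage cannot proceed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeltCurve:
    """Temperature series of the unfolding observable.

    Parameters
    ----------
    temperature_K : array-like
        Strictly increasing temperatures in Kelvin, within (250, 400).
    signal : array-like
        Observed mean residue molar ellipticity Y0 at the monitored
        wavelength, same length as ``temperature_K``.
    wavelength_nm : float
        Monitored wavelength (default 222 nm).
    """

    temperature_K: np.ndarray
    signal: np.ndarray
    wavelength_nm: float = 222.0

    def __post_init__(self):
        t = np.asarray(self.temperature_K, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("temperature and signal must be 1-D arrays of equal length")
        if t.size < 10:
            raise ValueError("a melt curve needs at least 10 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if t.min() <= 250.0 or t.max() >= 400.0:
            raise ValueError("temperatures must lie in (250, 400) K; convert from Celsius?")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in melt curve")
        object.__setattr__(self, "temperature_K", t)
        object.__setattr__(self, "signal", y)

    @classmethod
    def from_celsius(cls, temperature_C, signal, wavelength_nm: float = 222.0) -> "MeltCurve":
        return cls(np.asarray(temperature_C, dtype=float) + 273.15, signal, wavelength_nm)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, temp_unit: str = "K",
                       wavelength_nm: float = 222.0) -> "MeltCurve":
        """Build from a table with ``temperature`` and ``signal`` columns."""
        t = df["temperature"].to_numpy(dtype=float)
        y = df["signal"].to_numpy(dtype=float)
        order = np.argsort(t)
        t, y = t[order], y[order]
        if temp_unit.upper() == "C":
            t = t + 273.15
        elif temp_unit.upper() != "K":
            raise ValueError(f"unknown temperature unit {temp_unit!r}")
        return cls(t, y, wavelength_nm)

    @classmethod
    def from_csv(cls, path, temp_unit: str = "K", wavelength_nm: float = 222.0) -> "MeltCurve":
        df = pd.read_csv(path, sep=None, engine="python")
        df.columns = [c.strip().lower() for c in df.columns]
        return cls.from_dataframe(df, temp_unit=temp_unit, wavelength_nm=wavelength_nm)


@dataclass(frozen=True)
class BaselineModel:
    """Linear native and unfolded baselines, signal = intercept + slope*T."""

    y_N: float
    m_N: float
    y_U: float
    m_U: float
    native_window_K: tuple[float, float]
    unfolded_window_K: tuple[float, float]

    def __post_init__(self):
        if self.native_window_K[0] >= self.native_window_K[1]:
            raise ValueError("native window must be an increasing interval")
        if self.unfolded_window_K[0] >= self.unfolded_window_K[1]:
            raise ValueError("unfolded window must be an increasing interval")
        if self.native_window_K[1] > self.unfolded_window_K[0]:
            raise ValueError("native window must lie entirely below the unfolded window")

    def native(self, T):
        return self.y_N + self.m_N * np.asarray(T, dtype=float)

    def unfolded(self, T):
        return self.y_U + self.m_U * np.asarray(T, dtype=float)


@dataclass(frozen=True)
class StabilityCurve:
    """Unfolding free energies dG(T) restricted to the transition window."""

    temperature_K: np.ndarray
    dG_kJ_mol: np.ndarray
    window_K: tuple[float, float] = DEFAULT_TRANSITION_WINDOW

    def __post_init__(self):
        t = np.asarray(self.temperature_K, dtype=float)
        g = np.asarray(self.dG_kJ_mol, dtype=float)
        if t.shape != g.shape:
            raise ValueError("temperature and dG arrays must have the same shape")
        lo, hi = self.window_K
        if t.size and (t.min() < lo or t.max() > hi):
            raise ValueError("stability-curve temperatures must lie inside the window")
        object.__setattr__(self, "temperature_K", t)
        object.__setattr__(self, "dG_kJ_mol", g)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"temperature_K": self.temperature_K,
                             "dG_kJ_mol": self.dG_kJ_mol})


@dataclass(frozen=True)
class ThermoParams:
    """Fitted two-state thermodynamic parameters and derived quantities."""

    Tm_K: float
    dHm_kJ_mol: float
    dCp_kJ_mol_K: float
    Ts_K: float | None
    dG_at_ref_kJ_mol: float
    Tref_K: float = DEFAULT_TREF
    uncertainties: dict = field(default_factory=dict)
    fit_residual: float = float("nan")

    def __post_init__(self):
        if self.Tm_K <= 0:
            raise ValueError("Tm must be positive")
        if self.dCp_kJ_mol_K < 0:
            raise ValueError("dCp must be non-negative")
        if self.dCp_kJ_mol_K > 0 and self.Ts_K is not None and not self.Ts_K < self.Tm_K:
            raise ValueError("Ts must lie below Tm when dCp > 0")
        # midpoint identity: the stability curve vanishes at Tm by construction
        assert abs(gibbs_helmholtz(self.Tm_K, self.Tm_K, self.dHm_kJ_mol,
                                   self.dCp_kJ_mol_K)) < 1e-9


# ---------------------------------------------------------------------------
# closed-form pieces
# ---------------------------------------------------------------------------


def gibbs_helmholtz(T, Tm_K: float, dHm_kJ_mol: float, dCp_kJ_mol_K: float = 0.0):
    """Stability curve dG(T) = dHm(1 - T/Tm) + dCp[(T - Tm) - T ln(T/Tm)], in kJ/mol."""
    T = np.asarray(T, dtype=float)
    out = dHm_kJ_mol * (1.0 - T / Tm_K)
    if dCp_kJ_mol_K != 0.0:
        out = out + dCp_kJ_mol_K * ((T - Tm_K) - T * np.log(T / Tm_K))
    return out if out.ndim else float(out)


def stationary_temperature(Tm_K: float, dHm_kJ_mol: float, dCp_kJ_mol_K: float) -> float | None:
    """Temperature of maximum stability, Ts = Tm exp(-dHm/(dCp Tm)).

    Returns ``None`` when dCp <= 0 (the stability curve is then a straight
    van't Hoff line with no stationary point).
    """
    if dCp_kJ_mol_K <= 0:
        return None
    return Tm_K * math.exp(-dHm_kJ_mol / (dCp_kJ_mol_K * Tm_K))


def dcp_from_stationarity(Tm_K: float, dHm_kJ_mol: float, Ts_K: float) -> float:
    """Solve the stationarity condition d(dG)/dT|_Ts = 0 for dCp.

    Inverts Ts = Tm exp(-dHm/(dCp Tm)) to dCp = dHm / (Tm ln(Tm/Ts)).
    """
    if not 0 < Ts_K < Tm_K:
        raise ValueError("Ts must lie in (0, Tm)")
    return dHm_kJ_mol / (Tm_K * math.log(Tm_K / Ts_K))


def delta_g_at(T_K, params) -> float:
    """Evaluate the fitted stability curve at temperature ``T_K`` (kJ/mol)."""
    if np.any(np.asarray(T_K) <= 0):
        raise ValueError("temperature must be positive")
    return gibbs_helmholtz(T_K, params.Tm_K, params.dHm_kJ_mol, params.dCp_kJ_mol_K)


# ---------------------------------------------------------------------------
# staged pipeline operations
# ---------------------------------------------------------------------------


def fit_baselines(curve: MeltCurve, native_window_K: tuple[float, float],
                  unfolded_window_K: tuple[float, float]) -> BaselineModel:
    """Ordinary least-squares lines through the points inside each window."""
    if native_window_K[1] > unfolded_window_K[0]:
        raise MeltAnalysisError("baselines", "native window must lie below the unfolded window")
    t, y = curve.temperature_K, curve.signal
    coefs = []
    for name, (lo, hi) in (("native", native_window_K), ("unfolded", unfolded_window_K)):
        mask = (t >= lo) & (t <= hi)
        if mask.sum() < 3:
            raise MeltAnalysisError(
                "baselines", f"{name} window [{lo}, {hi}] K contains only "
                f"{int(mask.sum())} points (need >= 3)")
        slope, intercept = np.polyfit(t[mask], y[mask], 1)
        coefs.append((intercept, slope))
    (yN, mN), (yU, mU) = coefs
    return BaselineModel(yN, mN, yU, mU, tuple(native_window_K), tuple(unfolded_window_K))


def unfolded_fraction(curve: MeltCurve, baselines: BaselineModel,
                      eps: float = FRACTION_CLIP_EPS):
    """Unfolded fraction fU(T) from the baseline-corrected signal.

    Returns ``(fU, clipped)`` where ``clipped`` marks points pushed into
    [eps, 1 - eps]; clipped points are excluded from the stability fit
    downstream because their free energies are unbounded.
    """
    t = curve.temperature_K
    lo = baselines.native(t)
    hi = baselines.unfolded(t)
    denom = hi - lo
    if np.any(denom == 0) or np.any(np.sign(denom) != np.sign(denom[0])):
        raise MeltAnalysisError("fraction", "baseline lines cross inside the data range")
    f = (curve.signal - lo) / denom
    clipped = (f < eps) | (f > 1.0 - eps)
    return np.clip(f, eps, 1.0 - eps), clipped


def free_energy_series(fU, temperature_K, window_K=DEFAULT_TRANSITION_WINDOW,
                       exclude=None) -> StabilityCurve:
    """dG(T) = -R T ln[fU/(1-fU)] restricted to the transition window."""
    fU = np.asarray(fU, dtype=float)
    t = np.asarray(temperature_K, dtype=float)
    if np.any((fU <= 0) | (fU >= 1)):
        raise MeltAnalysisError("free_energy", "fU must lie strictly inside (0, 1)")
    keep = (t >= window_K[0]) & (t <= window_K[1])
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    if keep.sum() == 0:
        raise MeltAnalysisError(
            "free_energy", f"no usable points inside the transition window {window_K} K")
    K = fU[keep] / (1.0 - fU[keep])
    dG = -GAS_CONSTANT_KJ * t[keep] * np.log(K)
    return StabilityCurve(t[keep], dG, tuple(window_K))


def _vant_hoff_init(stability: StabilityCurve) -> tuple[float, float]:
    """Deterministic (Tm0, dHm0) start from the zero crossing and van't Hoff slope."""
    t, g = stability.temperature_K, stability.dG_kJ_mol
    sign = np.sign(g)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    if crossings.size:
        i = crossings[0]
        # linear interpolation of the dG = 0 crossing
        Tm0 = t[i] + (t[i + 1] - t[i]) * g[i] / (g[i] - g[i + 1])
    else:
        Tm0 = float(t[np.argmin(np.abs(g))])
    # van't Hoff slope of ln K vs 1/T over the central 20% of the transition
    lnK = -g / (GAS_CONSTANT_KJ * t)
    mid = np.abs(t - Tm0) <= 0.1 * (t[-1] - t[0])
    if mid.sum() >= 3:
        slope = np.polyfit(1.0 / t[mid], lnK[mid], 1)[0]
        dHm0 = -GAS_CONSTANT_KJ * slope
    else:
        dHm0 = 100.0
    if not np.isfinite(dHm0) or dHm0 <= 0:
        dHm0 = 100.0
    return float(Tm0), float(dHm0)


def fit_gibbs_helmholtz(stability: StabilityCurve, init=None,
                        tref_K: float = DEFAULT_TREF) -> ThermoParams:
    """Nonlinear least-squares fit of the Gibbs-Helmholtz curve to dG(T) points.

    Parameters are (Tm, dHm, dCp) with dCp constrained >= 0. Requires at
    least 6 points spanning both sides of the zero crossing so the midpoint
    is interpolated, not extrapolated.
    """
    t, g = stability.temperature_K, stability.dG_kJ_mol
    if t.size < 6:
        raise MeltAnalysisError("gibbs_helmholtz", "need >= 6 stability points")
    if not (g.min() < 0 < g.max()):
        raise MeltAnalysisError(
            "gibbs_helmholtz", "stability points must span both sides of dG = 0")
    if init is None:
        Tm0, dHm0 = _vant_hoff_init(stability)
        init = (Tm0, dHm0, 0.5)
    popt, pcov = optimize.curve_fit(
        gibbs_helmholtz, t, g, p0=init,
        bounds=([t.min() - 50.0, 1e-6, 0.0], [t.max() + 50.0, 1e4, 50.0]),
        maxfev=20000)
    Tm, dHm, dCp = map(float, popt)
    perr = np.sqrt(np.diag(pcov))
    resid = g - gibbs_helmholtz(t, *popt)
    return ThermoParams(
        Tm_K=Tm, dHm_kJ_mol=dHm, dCp_kJ_mol_K=dCp,
        Ts_K=stationary_temperature(Tm, dHm, dCp),
        dG_at_ref_kJ_mol=float(gibbs_helmholtz(tref_K, Tm, dHm, dCp)),
        Tref_K=tref_K,
        uncertainties={"Tm_K": float(perr[0]), "dHm_kJ_mol": float(perr[1]),
                       "dCp_kJ_mol_K": float(perr[2])},
        fit_residual=float(np.sqrt(np.mean(resid ** 2))))


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


def _two_state_signal(T, yN, mN, yU, mU, Tm, dHm, dCp):
    dG = gibbs_helmholtz(T, Tm, dHm, dCp)
    K = np.exp(-dG / (GAS_CONSTANT_KJ * T))
    fU = K / (1.0 + K)
    return (1.0 - fU) * (yN + mN * T) + fU * (yU + mU * T)


def _noise_floor(y: np.ndarray) -> float:
    """Robust per-point noise estimate from second differences.

    For a smooth signal with additive white noise of standard deviation
    sigma, the second differences have standard deviation sigma*sqrt(6);
    the MAD makes the estimate robust to the transition's curvature.
    """
    d2 = np.diff(y, 2)
    mad = 1.4826 * np.median(np.abs(d2 - np.median(d2)))
    return max(mad / math.sqrt(6.0), 1e-9 * max(1.0, float(np.abs(y).max())))


class TwoStateMeltModel:
    """Two-state unfolding model for a thermal melt.

    The fit proceeds in two stages. Stage one is the classical windowed
    pipeline: linear baselines are fitted inside the native and unfolded
    windows, the unfolded fraction and free-energy series are computed, and
    the Gibbs-Helmholtz curve is fitted over the transition window; this
    yields deterministic starting values. Stage two refits the raw signal
    Y0(T) globally over all seven parameters (four baseline coefficients and
    Tm, dHm, dCp), which removes the baseline-extrapolation bias that arises
    when a marginally stable protein is already partly unfolded at the
    lowest measured temperature.

    Parameters
    ----------
    curve : MeltCurve
    native_window_K, unfolded_window_K : (low, high) or None
        Baseline windows. Defaults: lowest 10 K and highest 15 K of the data.
    transition_window_K : (low, high)
        Temperature range of points entering the free-energy fit.
    tref_K : float
        Reference temperature at which dG is reported.
    """

    def __init__(self, curve: MeltCurve, native_window_K=None, unfolded_window_K=None,
                 transition_window_K=DEFAULT_TRANSITION_WINDOW, tref_K=DEFAULT_TREF):
        self.curve = curve
        t = curve.temperature_K
        self.transition_window_K = tuple(transition_window_K)
        # marginally stable proteins show no clean native plateau, so the
        # default baseline windows are generous: the lowest 15 K and all
        # data above the transition window (falling back to the top 15 K)
        self.native_window_K = tuple(native_window_K) if native_window_K is not None \
            else (float(t[0]), float(t[0]) + 15.0)
        if unfolded_window_K is not None:
            self.unfolded_window_K = tuple(unfolded_window_K)
        else:
            lo = self.transition_window_K[1]
            if np.sum(t >= lo) < 3 or lo <= self.native_window_K[1]:
                lo = float(t[-1]) - 15.0
            self.unfolded_window_K = (lo, float(t[-1]))
        self.tref_K = float(tref_K)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, temp_unit: str = "K", **kwargs):
        return cls(MeltCurve.from_dataframe(df, temp_unit=temp_unit), **kwargs)

    def _coarse_init(self):
        """Window-free starting values for the global fit.

        Used when the windowed staged pipeline degenerates (e.g. a marginally
        stable protein with no native plateau, where the apparent native
        baseline crosses the unfolded one): flat baselines at the curve ends
        and the signal-midpoint temperature as Tm0.
        """
        t, y = self.curve.temperature_K, self.curve.signal
        y0, y1 = float(y[:3].mean()), float(y[-3:].mean())
        mid = 0.5 * (y0 + y1)
        sign = np.sign(y - mid)
        cross = np.nonzero(np.diff(sign) != 0)[0]
        Tm0 = float(t[cross[0]]) if cross.size else float(t[t.size // 2])
        return [y0, 0.0, y1, 0.0, Tm0, 100.0, 0.5]

    def _profiled_refit(self, theta0, dcp_prior):
        """Penalized least squares over (Tm, dHm, dCp) with profiled baselines.

        For a candidate thermo vector the unfolded fraction is known, so the
        observed signal is linear in the four baseline coefficients; those
        are solved by linear least squares restricted to the baseline
        windows, and the whole-curve residual (scaled by the noise floor)
        drives the outer fit. An optional Gaussian prior on dCp, appended as
        one extra residual row, regularizes the heat-capacity term, which a
        single melt curve constrains only weakly; noise-free data overwhelm
        the prior automatically through the residual scaling.
        """
        t, y = self.curve.temperature_K, self.curve.signal
        wmask = (((t >= self.native_window_K[0]) & (t <= self.native_window_K[1]))
                 | ((t >= self.unfolded_window_K[0]) & (t <= self.unfolded_window_K[1])))
        sig = _noise_floor(y)

        def design(theta):
            dG = gibbs_helmholtz(t, theta[0], theta[1], theta[2])
            K = np.exp(-dG / (GAS_CONSTANT_KJ * t))
            fU = K / (1.0 + K)
            return np.column_stack([1.0 - fU, (1.0 - fU) * t, fU, fU * t])

        def profiled_baselines(theta):
            A = design(theta)
            coef, *_ = np.linalg.lstsq(A[wmask], y[wmask], rcond=None)
            return coef, A

        def residuals(theta):
            coef, A = profiled_baselines(theta)
            r = (y - A @ coef) / sig
            if dcp_prior is not None:
                r = np.append(r, (theta[2] - dcp_prior[0]) / dcp_prior[1])
            return r

        sol = optimize.least_squares(
            residuals, x0=theta0,
            bounds=([t.min() - 50.0, 1e-6, 0.0], [t.max() + 50.0, 1e4, 50.0]),
            xtol=1e-14, ftol=1e-14)
        Tm, dHm, dCp = map(float, sol.x)
        coef, A = profiled_baselines(sol.x)
        # covariance of the penalized fit in unit-noise scaling
        JtJ = sol.jac.T @ sol.jac
        try:
            perr = np.sqrt(np.diag(np.linalg.inv(JtJ)))
        except np.linalg.LinAlgError:
            perr = np.full(3, np.nan)
        rmse = float(np.sqrt(np.mean((y - A @ coef) ** 2)))
        params = ThermoParams(
            Tm_K=Tm, dHm_kJ_mol=dHm, dCp_kJ_mol_K=dCp,
            Ts_K=stationary_temperature(Tm, dHm, dCp),
            dG_at_ref_kJ_mol=float(gibbs_helmholtz(self.tref_K, Tm, dHm, dCp)),
            Tref_K=self.tref_K,
            uncertainties={"Tm_K": float(perr[0]), "dHm_kJ_mol": float(perr[1]),
                           "dCp_kJ_mol_K": float(perr[2])},
            fit_residual=rmse)
        baselines = BaselineModel(float(coef[0]), float(coef[1]), float(coef[2]),
                                  float(coef[3]), self.native_window_K,
                                  self.unfolded_window_K)
        return params, baselines

    def fit(self, refine: bool = True,
            dcp_prior: tuple[float, float] | None = (0.5, 0.3)) -> "MeltResults":
        """Fit the model.

        Parameters
        ----------
        refine : bool
            When True (default), follow the windowed staged pipeline with
            the profiled-baseline penalized refit, which removes the
            baseline-extrapolation bias of the windowed stages. When False,
            return the staged result unrefined.
        dcp_prior : (center, sd) or None
            Gaussian prior on dCp in kJ/mol/K used by the refinement
            (default (0.5, 0.3)); ``None`` fits dCp by maximum likelihood
            alone, which is poorly conditioned for a single melt curve.
        """
        curve = self.curve
        t = curve.temperature_K
        for name, (lo, hi) in (("native", self.native_window_K),
                               ("unfolded", self.unfolded_window_K)):
            if np.sum((t >= lo) & (t <= hi)) < 3:
                raise MeltAnalysisError(
                    "baselines", f"{name} baseline window [{lo}, {hi}] K holds "
                    "fewer than 3 points")
        if self.native_window_K[1] > self.unfolded_window_K[0]:
            raise MeltAnalysisError(
                "baselines", "baseline windows overlap: the curve does not span "
                f"both sides of the transition window {self.transition_window_K} K")
        lo, hi = self.transition_window_K
        if not np.any((t >= lo) & (t <= hi)):
            raise MeltAnalysisError(
                "free_energy", f"no data inside the transition window "
                f"[{lo}, {hi}] K")
        staged = None
        try:
            baselines = fit_baselines(curve, self.native_window_K,
                                      self.unfolded_window_K)
            fU, clipped = unfolded_fraction(curve, baselines)
            stability = free_energy_series(fU, curve.temperature_K,
                                           self.transition_window_K, exclude=clipped)
            staged = fit_gibbs_helmholtz(stability, tref_K=self.tref_K)
        except MeltAnalysisError:
            if not refine:
                raise

        params = staged
        if refine:
            if staged is not None:
                theta0 = [staged.Tm_K, staged.dHm_kJ_mol,
                          max(staged.dCp_kJ_mol_K, 1e-3)]
            else:
                theta0 = self._coarse_init()[4:7]
            params, baselines = self._profiled_refit(theta0, dcp_prior)
            fU, clipped = unfolded_fraction(curve, baselines)
            stability = free_energy_series(fU, curve.temperature_K,
                                           self.transition_window_K, exclude=clipped)

        return MeltResults(model=self, params=params, staged_params=staged,
                           baselines=baselines, fraction_unfolded=fU,
                           clipped=clipped, stability=stability)


@dataclass(frozen=True)
class MeltResults:
    """Fit results for a :class:`TwoStateMeltModel`."""

    model: TwoStateMeltModel
    params: ThermoParams
    #: result of the windowed staged pipeline, or None when it degenerated
    #: and the global fit started from the coarse initialization
    staged_params: ThermoParams | None
    baselines: BaselineModel
    fraction_unfolded: np.ndarray
    clipped: np.ndarray
    stability: StabilityCurve

    @property
    def n_clipped(self) -> int:
        return int(np.sum(self.clipped))

    @property
    def bse(self) -> dict:
        """Standard errors of (Tm, dHm, dCp) from the fit covariance."""
        return dict(self.params.uncertainties)

    def predict(self, T_K=None):
        """Model signal Y0(T) at the fitted parameters."""
        if T_K is None:
            T_K = self.model.curve.temperature_K
        p, b = self.params, self.baselines
        return _two_state_signal(np.asarray(T_K, dtype=float), b.y_N, b.m_N, b.y_U,
                                 b.m_U, p.Tm_K, p.dHm_kJ_mol, p.dCp_kJ_mol_K)

    def to_frame(self) -> pd.DataFrame:
        """Per-temperature table of (T, Y0, fU, dG where defined)."""
        curve = self.model.curve
        dG = np.full_like(curve.temperature_K, np.nan)
        idx = np.searchsorted(curve.temperature_K, self.stability.temperature_K)
        dG[idx] = self.stability.dG_kJ_mol
        return pd.DataFrame({
            "temperature_K": curve.temperature_K,
            "signal": curve.signal,
            "fraction_unfolded": self.fraction_unfolded,
            "dG_kJ_mol": dG,
        })

    def report(self) -> dict:
        """JSON-serializable summary of the whole analysis."""
        p = self.params
        return {
            "Tm_K": p.Tm_K,
            "dHm_kJ_mol": p.dHm_kJ_mol,
            "dCp_kJ_mol_K": p.dCp_kJ_mol_K,
            "Ts_K": p.Ts_K,
            "Tref_K": p.Tref_K,
            "dG_at_ref_kJ_mol": p.dG_at_ref_kJ_mol,
            "uncertainties": p.uncertainties,
            "fit_residual": p.fit_residual,
            "baselines": {
                "y_N": self.baselines.y_N, "m_N": self.baselines.m_N,
                "y_U": self.baselines.y_U, "m_U": self.baselines.m_U,
            },
            "windows_K": {
                "native": list(self.model.native_window_K),
                "unfolded": list(self.model.unfolded_window_K),
                "transition": list(self.model.transition_window_K),
            },
            "n_points": int(self.model.curve.temperature_K.size),
            "n_clipped": self.n_clipped,
        }

    def summary(self) -> str:
        """Human-readable parameter table."""
        p = self.params
        u = p.uncertainties
        buf = _io.StringIO()
        buf.write("Two-state thermal unfolding fit\n")
        buf.write("=" * 46 + "\n")
        rows = [
            ("Tm (K)", p.Tm_K, u.get("Tm_K")),
            ("dHm (kJ/mol)", p.dHm_kJ_mol, u.get("dHm_kJ_mol")),
            ("dCp (kJ/mol/K)", p.dCp_kJ_mol_K, u.get("dCp_kJ_mol_K")),
            ("Ts (K)", p.Ts_K, None),
            (f"dG({p.Tref_K:g} K) (kJ/mol)", p.dG_at_ref_kJ_mol, None),
        ]
        for name, val, err in rows:
            v = "undefined" if val is None else f"{val:12.3f}"
            e = f"  +/- {err:.3f}" if err is not None else ""
            buf.write(f"{name:<24s}{v}{e}\n")
        buf.write("-" * 46 + "\n")
        buf.write(f"points: {self.model.curve.temperature_K.size}   "
                  f"clipped: {self.n_clipped}   "
                  f"rmse: {p.fit_residual:.4g}\n")
        return buf.getvalue()


def analyze_melt(curve: MeltCurve, native_window_K=None, unfolded_window_K=None,
                 transition_window_K=DEFAULT_TRANSITION_WINDOW,
                 tref_K=DEFAULT_TREF, refine: bool = True) -> MeltResults:
    """Full melt analysis: baselines -> fU -> dG(T) -> Gibbs-Helmholtz fit.

    Convenience wrapper over :class:`TwoStateMeltModel`.
    """
    model = TwoStateMeltModel(curve, native_window_K=native_window_K,
                              unfolded_window_K=unfolded_window_K,
                              transition_window_K=transition_window_K, tref_K=tref_K)
    return model.fit(refine=refine)
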