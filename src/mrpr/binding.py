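"""Biophysical binding and stability models.

Two measurement types are modelled:

* Isothermal titration calorimetry (ITC) under the single-class
  independent-sites ("one set of sites", Wiseman) isotherm, with the
  standard displaced-volume accounting for an overflow cell.  The cell
  holds the macromolecule (here an operator DNA duplex) and the syringe
  holds the titrant protein.
* Label-free differential scanning fluorimetry (nanoDSF) unfolding
  curves, fitted with a two-baseline Boltzmann sigmoid whose inflection
  point is the melting temperature Tm.

Both fitters are scikit-learn style estimators; :func:`fit_itc` and
:func:`fit_dsf` are thin functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .exceptions import FitError, InputError

__all__ = [
    "InjectionSchedule",
    "ITCModelParams",
    "ITCFit",
    "TitrationExperiment",
    "MeltCurve",
    "BoltzmannParams",
    "isotherm_heats",
    "OneSiteBindingModel",
    "BoltzmannMelt",
    "fit_itc",
    "fit_dsf",
]

#: kcal -> microcal conversion folded with the 1e-12 from (uM * ul -> mol)
_UCAL_PER_UM_UL_KCAL = 1e-3


def _default_injections() -> list[float]:
    # priming injection followed by twelve full injections
    return [0.4] + [3.0] * 12


@dataclass
class InjectionSchedule:
    """ITC injection schedule and cell/syringe contents.

    Parameters
    ----------
    cell_volume
        Working cell volume V0 in microliters.
    injection_volumes
        Per-injection volumes in microliters.  The default is the
        13-injection protocol: one 0.4 ul priming injection followed by
        twelve 3 ul injections.
    cell_conc
        Macromolecule (DNA) concentration in the cell, uM.
    syringe_conc
        Titrant (protein) concentration in the syringe, uM.
    """

    cell_volume: float = 200.0
    injection_volumes: list[float] = field(default_factory=_default_injections)
    cell_conc: float = 20.0
    syringe_conc: float = 250.0

    def __post_init__(self) -> None:
        vols = np.asarray(self.injection_volumes, dtype=float)
        if vols.size == 0 or np.any(vols <= 0):
            raise InputError("injection volumes must be positive and non-empty")
        if self.cell_volume <= 0:
            raise InputError("cell_volume must be positive")
        if self.cell_conc <= 0 or self.syringe_conc < 0:
            raise InputError("concentrations must be positive (syringe may be 0)")
        self.injection_volumes = [float(v) for v in vols]

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)


@dataclass
class ITCModelParams:
    """One-set-of-sites parameters: stoichiometry n, Kd (uM), dH (kcal/mol)."""

    n: float = 1.0
    kd: float = 1.0
    dh: float = -10.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise InputError("stoichiometry n must be positive")
        if self.kd <= 0:
            raise InputError("kd must be positive")


@dataclass
class TitrationExperiment:
    """Observed (or simulated) per-injection heats under a schedule."""

    schedule: InjectionSchedule
    heats: np.ndarray  # ucal, one per injection
    true_params: ITCModelParams | None = None

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        if self.heats.shape != (self.schedule.n_injections,):
            raise InputError("heats must have one entry per injection")


@dataclass
class ITCFit:
    params: ITCModelParams
    std_errors: dict[str, float]
    residual_norm: float
    n_excluded_injections: int


@dataclass
class MeltCurve:
    """nanoDSF unfolding curve: F350/F330 ratio on a temperature grid (deg C)."""

    temperature: np.ndarray
    ratio: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.temperature.ndim != 1 or self.temperature.shape != self.ratio.shape:
            raise InputError("temperature and ratio must be matching 1-D arrays")
        if np.any(np.diff(self.temperature) <= 0):
            raise InputError("temperature grid must be strictly increasing")


@dataclass
class BoltzmannParams:
    """Two-baseline sigmoid: ratio(T) = low + (high-low)/(1+exp((tm-T)/slope))."""

    tm: float
    slope: float
    low: float
    high: float
    std_errors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise InputError("slope must be nonzero")


def isotherm_heats(params: ITCModelParams, schedule: InjectionSchedule) -> np.ndarray:
    """Per-injection heats (ucal) of the one-set-of-sites isotherm.

    After injection i the cumulative injected volume is dV_i.  Overflow
    dilution follows the standard perfusion correction: material expelled
    during an injection is accounted at the average of the pre- and
    post-injection concentrations, giving

        M_i = M0 (1 - dV_i/2V0) / (1 + dV_i/2V0)     (cell macromolecule)
        X_i = X0 (dV_i/V0)      / (1 + dV_i/2V0)     (titrant)

    The bound-site fraction theta_i solves the single-site mass-action
    quadratic, the cumulative heat is Q_i = n theta_i M_i V0 dH, and the
    observed heat of injection i is the cumulative difference plus the
    heat carried out with the displaced volume.
    """
    v0 = schedule.cell_volume
    vols = np.asarray(schedule.injection_volumes, dtype=float)
    dv = np.cumsum(vols)
    m = schedule.cell_conc * (1.0 - dv / (2.0 * v0)) / (1.0 + dv / (2.0 * v0))
    x = schedule.syringe_conc * (dv / v0) / (1.0 + dv / (2.0 * v0))

    nm = params.n * m
    b = 1.0 + x / nm + params.kd / nm
    theta = (b - np.sqrt(b * b - 4.0 * x / nm)) / 2.0

    q = params.n * theta * m * v0 * params.dh * _UCAL_PER_UM_UL_KCAL
    q_prev = np.concatenate([[0.0], q[:-1]])
    return q - q_prev + (vols / v0) * (q + q_prev) / 2.0


class OneSiteBindingModel(BaseEstimator):
    """Least-squares fitter for the one-set-of-sites ITC isotherm.

    Kd is fitted in log10 space with multi-start initialization over a
    fixed grid of Kd decades; the start grid is deterministic, so fits
    are reproducible.  The first (priming) injection is excluded by
    default.

    Parameters
    ----------
    exclude_first : bool, default True
        Drop the small priming injection from the residuals.
    kd_bounds : tuple of float
        Allowed Kd range in uM.
    n_bounds : tuple of float
        Allowed stoichiometry range.

    Attributes
    ----------
    n_, kd_, dh_ : float
        Fitted stoichiometry, Kd (uM) and enthalpy (kcal/mol).
    std_errors_ : dict
        Asymptotic standard errors for n, kd and dh.
    residual_norm_ : float
        Euclidean norm of the residuals at the optimum.
    """

    def __init__(
        self,
        exclude_first: bool = True,
        kd_bounds: tuple[float, float] = (1e-4, 1e4),
        n_bounds: tuple[float, float] = (0.1, 10.0),
    ) -> None:
        self.exclude_first = exclude_first
        self.kd_bounds = kd_bounds
        self.n_bounds = n_bounds

    def fit(self, experiment: TitrationExperiment) -> "OneSiteBindingModel":
        schedule = experiment.schedule
        heats = experiment.heats
        mask = np.ones(len(heats), dtype=bool)
        n_excluded = 0
        if self.exclude_first:
            mask[0] = False
            n_excluded = 1
        if mask.sum() < 5:
            raise InputError("need at least 5 usable injections to fit")
        obs = heats[mask]

        lo = np.array([self.n_bounds[0], np.log10(self.kd_bounds[0]), -np.inf])
        hi = np.array([self.n_bounds[1], np.log10(self.kd_bounds[1]), np.inf])

        def residuals(x: np.ndarray) -> np.ndarray:
            p = ITCModelParams(n=x[0], kd=10.0 ** x[1], dh=x[2])
            return isotherm_heats(p, schedule)[mask] - obs

        # crude dH guess from the total heat assuming full saturation
        dh0 = heats.sum() / (
            schedule.cell_volume * schedule.cell_conc * _UCAL_PER_UM_UL_KCAL
        )
        if dh0 == 0:
            dh0 = -1.0
        best = None
        for log_kd0 in (-2.0, -1.0, 0.0, 1.0, 2.0):
            x0 = np.array([1.0, log_kd0, dh0])
            try:
                sol = optimize.least_squares(
                    residuals, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
                )
            except Exception:  # pragma: no cover - pathological start
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not best.success:
            raise FitError("one-set-of-sites fit did not converge from any start")

        n_fit, log_kd, dh = best.x
        self.n_ = float(n_fit)
        self.kd_ = float(10.0 ** log_kd)
        self.dh_ = float(dh)
        self.residual_norm_ = float(np.sqrt(2.0 * best.cost))
        self.n_excluded_injections_ = n_excluded

        dof = obs.size - 3
        jac = best.jac
        jtj = jac.T @ jac
        try:
            cov = np.linalg.inv(jtj) * (2.0 * best.cost / max(dof, 1))
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(3, np.inf)
        self.std_errors_ = {
            "n": float(se[0]),
            "kd": float(self.kd_ * np.log(10.0) * se[1]),
            "dh": float(se[2]),
        }
        return self

    def predict(self, schedule: InjectionSchedule) -> np.ndarray:
        """Model heats for a schedule at the fitted parameters."""
        p = ITCModelParams(n=self.n_, kd=self.kd_, dh=self.dh_)
        return isotherm_heats(p, schedule)

    def result_(self) -> ITCFit:
        return ITCFit(
            params=ITCModelParams(n=self.n_, kd=self.kd_, dh=self.dh_),
            std_errors=self.std_errors_,
            residual_norm=self.residual_norm_,
            n_excluded_injections=self.n_excluded_injections_,
        )


def boltzmann(t: np.ndarray, tm: float, slope: float, low: float, high: float) -> np.ndarray:
    """Two-baseline Boltzmann sigmoid evaluated on temperatures ``t``."""
    return low + (high - low) / (1.0 + np.exp((tm - np.asarray(t, float)) / slope))


class BoltzmannMelt(BaseEstimator):
    """Boltzmann-sigmoid fitter for nanoDSF melt curves.

    Tm is reported as the inflection point of the fitted sigmoid.
    Initialization takes the baselines from the curve ends and Tm from
    the temperature of maximal derivative, which makes the fit
    deterministic.

    Attributes
    ----------
    tm_, slope_, low_, high_ : float
        Fitted sigmoid parameters (tm and slope in deg C).
    std_errors_ : dict
        Asymptotic standard errors per parameter.
    """

    def __init__(self, edge_points: int = 5) -> None:
        self.edge_points = edge_points

    def fit(self, curve: MeltCurve) -> "BoltzmannMelt":
        t, r = curve.temperature, curve.ratio
        if t.size < 10:
            raise InputError("need at least 10 points spanning the transition")
        k = min(self.edge_points, t.size // 4)
        low0 = float(np.mean(r[:k]))
        high0 = float(np.mean(r[-k:]))
        grad = np.gradient(r, t)
        tm0 = float(t[np.argmax(np.abs(grad))])
        span = abs(high0 - low0)
        if span < 10 * max(np.std(np.diff(r)), 1e-12) and span < 1e-6:
            raise FitError("no unfolding transition detected (flat curve)")
        slope0 = max((t[-1] - t[0]) / 30.0, 1e-3)
        try:
            popt, pcov = optimize.curve_fit(
                boltzmann,
                t,
                r,
                p0=[tm0, slope0, low0, high0],
                maxfev=20000,
                xtol=1e-14,
                ftol=1e-14,
            )
        except RuntimeError as exc:
            raise FitError(f"Boltzmann fit did not converge: {exc}") from exc
        if popt[1] == 0:
            raise FitError("degenerate fit: zero slope")
        se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
        self.tm_ = float(popt[0])
        self.slope_ = float(popt[1])
        self.low_ = float(popt[2])
        self.high_ = float(popt[3])
        self.std_errors_ = dict(zip(("tm", "slope", "low", "high"), map(float, se)))
        return self

    def predict(self, temperature: np.ndarray) -> np.ndarray:
        return boltzmann(temperature, self.tm_, self.slope_, self.low_, self.high_)

    def result_(self) -> BoltzmannParams:
        return BoltzmannParams(
            tm=self.tm_,
            slope=self.slope_,
            low=self.low_,
            high=self.high_,
            std_errors=self.std_errors_,
        )


def fit_itc(experiment: TitrationExperiment, exclude_first: bool = True) -> ITCFit:
    """Fit the one-set-of-sites isotherm to an ITC experiment."""
    return OneSiteBindingModel(exclude_first=exclude_first).fit(experiment).result_()


def fit_dsf(curve: MeltCurve) -> BoltzmannParams:
    """Fit the Boltzmann sigmoid to a melt curve; Tm is the inflection point."""
    return BoltzmannMelt().fit(curve).result_()
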