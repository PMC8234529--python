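"""Three-element generalized Kelvin-Voigt creep model and its fitting.

A spring (modulus E1) in series with a Voigt element (spring E2 parallel
to a dashpot of viscosity eta) creeps under a constant stress sigma0 as

    gamma(t) = sigma0/E1 + (sigma0/E2) * (1 - exp(-t/tau)),   tau = eta/E2.

``tau`` (the delay time, minutes here) is the time constant of the Voigt
element: a delay time small relative to the loading period means the gel
reaches its creep plateau almost immediately, so the shear transferred to
cells by ongoing horizontal gel flow is negligible.

Fitting is nonlinear least squares with the Levenberg-Marquardt algorithm
on log-parameters, which keeps the optimizer unconstrained while enforcing
E1, E2, eta > 0. Goodness of fit is summarised by Pearson's correlation
coefficient between observed and fitted strain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "KelvinVoigtParams",
    "CreepCurve",
    "KelvinVoigtFit",
    "KelvinVoigtRegressor",
    "kv_strain",
    "delay_time",
    "fit_kv",
    "creep_analysis",
    "creep_batch",
]

MAX_ITER = 500
GTOL = 1e-10


@dataclass(frozen=True)
class KelvinVoigtParams:
    """Model parameters: stress in Pa, moduli in Pa, viscosity in Pa*min."""

    sigma0: float
    E1: float
    E2: float
    eta: float

    def __post_init__(self) -> None:
        for name in ("sigma0", "E1", "E2", "eta"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def tau(self) -> float:
        """Delay time eta/E2 (min)."""
        return self.eta / self.E2

    @property
    def gamma_inf(self) -> float:
        """Creep plateau sigma0/E1 + sigma0/E2."""
        return self.sigma0 / self.E1 + self.sigma0 / self.E2


@dataclass
class CreepCurve:
    """Sampled creep response: times (min, strictly increasing, t[0] >= 0)
    and representative strain gamma (dimensionless)."""

    t: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        if self.t.shape != self.gamma.shape or self.t.ndim != 1:
            raise ValueError("t and gamma must be 1-D arrays of equal length")
        if self.t[0] < 0 or (len(self.t) > 1 and not np.all(np.diff(self.t) > 0)):
            raise ValueError("t must be nonnegative and strictly increasing")


@dataclass
class KelvinVoigtFit:
    params: KelvinVoigtParams
    tau: float
    fit_index: float
    converged: bool
    n_iter: int
    gamma_fitted: np.ndarray
    t_fitted: np.ndarray


def delay_time(E2: float, eta: float) -> float:
    """Delay time tau = eta / E2 (min); the Voigt time constant."""
    if E2 <= 0:
        raise ValueError("E2 must be strictly positive")
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    return eta / E2


def kv_strain(t, params: KelvinVoigtParams):
    """Creep strain of the three-element model at time(s) ``t`` (min)."""
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    g = params.sigma0 / params.E1 + (params.sigma0 / params.E2) * (
        1.0 - np.exp(-t / params.tau)
    )
    return g if g.ndim else float(g)


class KelvinVoigtRegressor:
    """Least-squares Kelvin-Voigt creep fit, sklearn-estimator style.

    Parameters
    ----------
    sigma0 : float
        Applied constant stress (Pa); known from the loading hardware and
        held fixed, so only E1, E2 and eta are free.
    init : KelvinVoigtParams, optional
        Starting point; when omitted a data-driven start is used
        (E1 from the first positive strain, E2 from the strain rise,
        eta from a time constant of one third of the record).
    drop_preload_zero : bool, default True
        Exclude a leading (t=0, gamma=0) sample from the residuals. Such a
        sample is the pre-load reference state, which the creep law — whose
        elastic branch responds instantaneously — does not describe.
    max_iter, gtol : Levenberg-Marquardt stopping controls.

    Attributes (after ``fit``)
    --------------------------
    E1_, E2_, eta_ : fitted parameters; tau_ = eta_/E2_ (min);
    fit_index_ : Pearson r between observed and fitted strain;
    converged_, n_iter_ : optimizer status.
    """

    def __init__(self, sigma0: float, init: KelvinVoigtParams | None = None,
                 drop_preload_zero: bool = True,
                 max_iter: int = MAX_ITER, gtol: float = GTOL):
        self.sigma0 = sigma0
        self.init = init
        self.drop_preload_zero = drop_preload_zero
        self.max_iter = max_iter
        self.gtol = gtol

    # minimal get/set_params so the estimator composes with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return {
            "sigma0": self.sigma0,
            "init": self.init,
            "drop_preload_zero": self.drop_preload_zero,
            "max_iter": self.max_iter,
            "gtol": self.gtol,
        }

    def set_params(self, **kw) -> "KelvinVoigtRegressor":
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _initial_guess(self, t: np.ndarray, g: np.ndarray) -> np.ndarray:
        if self.init is not None:
            p = self.init
            return np.log([p.E1, p.E2, p.eta])
        pos = g > 0
        if not pos.any():
            raise ValueError("degenerate curve: no positive strain samples")
        e1 = self.sigma0 / g[pos][0]
        rise = g[-1] - g[pos][0]
        e2 = self.sigma0 / rise if rise > 0 else e1
        eta = e2 * max(t[-1] / 3.0, 1e-6)
        return np.log([e1, e2, eta])

    def fit(self, t, gamma) -> "KelvinVoigtRegressor":
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be strictly positive")
        curve = CreepCurve(np.asarray(t, float), np.asarray(gamma, float))
        t, g = curve.t, curve.gamma
        if self.drop_preload_zero and t[0] == 0 and g[0] == 0:
            t, g = t[1:], g[1:]
        if len(t) < 5:
            raise ValueError("creep fitting needs >= 5 samples")
        if np.ptp(g) == 0:
            raise ValueError("degenerate curve: constant strain")

        s0 = self.sigma0

        def residuals(logp: np.ndarray) -> np.ndarray:
            e1, e2, eta = np.exp(logp)
            model = s0 / e1 + (s0 / e2) * (1.0 - np.exp(-t * e2 / eta))
            return model - g

        res = optimize.least_squares(
            residuals,
            self._initial_guess(t, g),
            method="lm",
            gtol=self.gtol,
            xtol=1e-14,
            ftol=1e-14,
            max_nfev=self.max_iter * 4,
        )
        e1, e2, eta = np.exp(res.x)
        self.E1_, self.E2_, self.eta_ = float(e1), float(e2), float(eta)
        self.tau_ = self.eta_ / self.E2_
        self.converged_ = bool(res.status > 0)
        self.n_iter_ = int(res.nfev)
        self.t_fit_ = t
        fitted = g + res.fun
        self.gamma_fit_ = fitted
        if np.ptp(fitted) == 0:  # flat model curve: correlation undefined
            self.fit_index_ = 0.0
        else:
            self.fit_index_ = float(stats.pearsonr(g, fitted).statistic)
        return self

    def predict(self, t) -> np.ndarray:
        if not hasattr(self, "E1_"):
            raise RuntimeError("estimator is not fitted")
        return kv_strain(np.asarray(t, float), self.params_)

    @property
    def params_(self) -> KelvinVoigtParams:
        return KelvinVoigtParams(self.sigma0, self.E1_, self.E2_, self.eta_)


def fit_kv(
    curve: CreepCurve,
    sigma0: float,
    init: KelvinVoigtParams | None = None,
    drop_preload_zero: bool = True,
) -> KelvinVoigtFit:
    """Fit the three-element model to a creep curve; see
    :class:`KelvinVoigtRegressor` for the procedure.

    Non-convergence is reported through ``converged=False`` rather than an
    exception; a constant curve raises.
    """
    est = KelvinVoigtRegressor(sigma0, init=init, drop_preload_zero=drop_preload_zero)
    est.fit(curve.t, curve.gamma)
    return KelvinVoigtFit(
        params=est.params_,
        tau=est.tau_,
        fit_index=est.fit_index_,
        converged=est.converged_,
        n_iter=est.n_iter_,
        gamma_fitted=est.gamma_fit_,
        t_fitted=est.t_fit_,
    )


def creep_analysis(
    sequence,
    sigma0: float,
    subset_size: int = 31,
    spacing: int = 16,
    search_radius: int = 10,
    convention: str = "euclidean",
) -> tuple[CreepCurve, KelvinVoigtFit]:
    """Creep curve and Kelvin-Voigt fit from a speckle time-lapse.

    Every frame k > 0 is correlated against frame 0 (DIC), reduced to a
    Green-Lagrange strain field and then to the representative strain
    gamma(t_k); the pre-load point (t_0, 0) is recorded in the curve but,
    being off-model for the creep law, excluded from the fit residuals.
    """
    from . import dic_strain  # local import: keeps module layering one-way

    frames = np.asarray(sequence.frames, dtype=np.float64)
    times = np.asarray(sequence.times, dtype=np.float64)
    if len(frames) < 5:
        raise ValueError("creep analysis needs >= 5 frames")
    grid = dic_strain.build_grid(frames[0].shape, subset_size, spacing, search_radius)
    gamma = [0.0]
    for k in range(1, len(frames)):
        field = dic_strain.displacement_field(frames[0], frames[k], grid)
        strain = dic_strain.green_lagrange(field)
        gamma.append(dic_strain.representative_strain(strain, convention))
    curve = CreepCurve(times, np.asarray(gamma))
    return curve, fit_kv(curve, sigma0)


def creep_batch(sequences, sigma0: float, **kwargs):
    """Fit several creep sequences; returns (per-sample DataFrame, summary).

    The summary row carries the medians of tau and the Pearson fit index —
    the two batch quantities reported for repeated gel specimens.
    """
    import pandas as pd

    rows = []
    for i, seq in enumerate(sequences):
        _, fit = creep_analysis(seq, sigma0, **kwargs)
        rows.append(
            {
                "sample": i,
                "E1": fit.params.E1,
                "E2": fit.params.E2,
                "eta": fit.params.eta,
                "tau_min": fit.tau,
                "pearson_r": fit.fit_index,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows)
    summary = {
        "n": len(table),
        "median_tau_min": float(table["tau_min"].median()),
        "median_pearson_r": float(table["pearson_r"].median()),
    }
    return table, summary
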