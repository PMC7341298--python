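"""Per-bird nonlinear least-squares Gompertz fitting and diagnostics.

The central objects follow the model/results convention: a
:class:`GompertzModel` is built from one bird's time/weight series and its
:meth:`~GompertzModel.fit` returns a :class:`GompertzResults` carrying the
estimates, derived maturity traits, goodness of fit and a ``summary()``
table.  :func:`fit_flock` maps the fit over a collection of trajectories and
returns a tidy per-bird parameter table.

Fitting is unweighted least squares (scipy trust-region reflective with box
bounds that keep the asymptote from collapsing onto biphasic data).  Both
curve forms are fitted directly in their own parameterization, as one would
when comparing them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .gompertz import (
    DEFAULT_SLAUGHTER_AGE,
    DerivedTraits,
    G1Params,
    G2Params,
    convert_g1_to_g2,
    convert_g2_to_g1,
    derive_from_g1,
    derive_from_g2,
    predict_g1,
    predict_g2,
)

__all__ = [
    "Trajectory",
    "GompertzModel",
    "GompertzResults",
    "fit_trajectory",
    "fit_flock",
    "goodness",
    "weekly_correlation",
    "parameter_correlations",
    "FALLBACK_INIT",
]

N_PARAMS = 3
MIN_POINTS_TRAJECTORY = 5  # biweekly designs have 17; below 5 a fit is not trusted

#: fixed defaults used when a trajectory is too degenerate to self-start
FALLBACK_INIT = G1Params(bwa=2500.0, b=3.5, k=0.015)


@dataclass(frozen=True)
class Trajectory:
    """One bird's longitudinal weight record.

    times are ages in days (strictly increasing, hatch = 0 allowed),
    weights in grams.
    """

    bird_id: str
    breed: str
    sex: str
    times: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "weights", w)
        if t.ndim != 1 or w.ndim != 1 or t.shape != w.shape:
            raise ValueError("times and weights must be 1-D and of equal length")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(w)):
            raise ValueError("times and weights must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing (no duplicate ages)")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")

    @property
    def n_obs(self) -> int:
        return int(self.times.size)


def _g1_residuals(theta: np.ndarray, t: np.ndarray, w: np.ndarray) -> np.ndarray:
    bwa, b, k = theta
    return bwa * np.exp(-b * np.exp(-k * t)) - w


def _g2_residuals(theta: np.ndarray, t: np.ndarray, w: np.ndarray) -> np.ndarray:
    bwa, mu, lam = theta
    return bwa * np.exp(-np.exp((np.e * mu / bwa) * (lam - t) + 1.0)) - w


class GompertzModel:
    """Gompertz growth model for one weight series.

    Parameters
    ----------
    times, weights : array-like
        Ages in days and body weights in g.  At least 3 points (the number
        of curve parameters); trajectory-level helpers require 5.
    model : {"g1", "g2"}
        Which parameterization to fit: classic (``g1``) or lag-time (``g2``).
    """

    def __init__(self, times, weights, model: str = "g1") -> None:
        model = model.lower()
        if model not in ("g1", "g2"):
            raise ValueError(f"model must be 'g1' or 'g2', got {model!r}")
        self.model_tag = model
        self.times = np.asarray(times, dtype=float)
        self.weights = np.asarray(weights, dtype=float)
        if self.times.size != self.weights.size or self.times.ndim != 1:
            raise ValueError("times and weights must be 1-D of equal length")
        if self.times.size < N_PARAMS:
            raise ValueError(f"need at least {N_PARAMS} observations, got {self.times.size}")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")
        self.labels: dict[str, str] = {}

    @classmethod
    def from_trajectory(cls, trajectory: Trajectory, model: str = "g1") -> "GompertzModel":
        if trajectory.n_obs < MIN_POINTS_TRAJECTORY:
            raise ValueError(
                f"trajectory {trajectory.bird_id!r} has {trajectory.n_obs} points; "
                f"at least {MIN_POINTS_TRAJECTORY} are required for fitting"
            )
        obj = cls(trajectory.times, trajectory.weights, model=model)
        obj.labels = {
            "bird_id": trajectory.bird_id,
            "breed": trajectory.breed,
            "sex": trajectory.sex,
        }
        return obj

    # -- initialisation -------------------------------------------------

    def default_init(self) -> G1Params | G2Params:
        """Self-starting values.

        BWa0 = 1.2 * max weight; b0 from the first weight; k0 from an
        ordinary regression of ln(-ln(w/BWa0)) on time.  Falls back to fixed
        defaults on degenerate input.
        """
        w = self.weights
        t = self.times
        bwa0 = 1.2 * float(w.max())
        init = FALLBACK_INIT
        if w[0] < bwa0:
            b0 = float(np.log(bwa0 / w[0]))
            # linearization: ln(-ln(w/BWa0)) = ln(b) - k t
            ratio = w / bwa0
            ok = (ratio > 0) & (ratio < 1)
            if ok.sum() >= 2:
                z = np.log(-np.log(ratio[ok]))
                slope, _ = np.polyfit(t[ok], z, 1)
                k0 = -float(slope)
                if 1e-4 < k0 < 1.0 and 0.1 < b0 <= 20.0:
                    init = G1Params(bwa=bwa0, b=b0, k=k0)
        if self.model_tag == "g2":
            return convert_g1_to_g2(init)
        return init

    # -- fitting ---------------------------------------------------------

    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        wmax = float(self.weights.max())
        if self.model_tag == "g1":
            lo = np.array([wmax, 0.1, 1e-4])
            hi = np.array([10.0 * wmax, 20.0, 1.0])
        else:
            # image of the g1 box under the reparameterization, loosened
            lo = np.array([wmax, 1e-3, -500.0])
            hi = np.array([10.0 * wmax, 10.0 * wmax / np.e, 500.0])
        return lo, hi

    def fit(
        self,
        init: G1Params | G2Params | None = None,
        t_slaughter: float = DEFAULT_SLAUGHTER_AGE,
        max_nfev: int = 2000,
    ) -> "GompertzResults":
        """Least-squares fit; never raises on non-convergence (flagged)."""
        if init is None:
            init = self.default_init()
        if self.model_tag == "g1":
            if isinstance(init, G2Params):
                init = convert_g2_to_g1(init)
            theta0 = np.array([init.bwa, init.b, init.k])
            resid = _g1_residuals
        else:
            if isinstance(init, G1Params):
                init = convert_g1_to_g2(init)
            theta0 = np.array([init.bwa, init.mu, init.lam])
            resid = _g2_residuals

        lo, hi = self._bounds()
        theta0 = np.clip(theta0, lo + 1e-9 * np.abs(lo), hi - 1e-9 * np.abs(hi))

        w_range = float(self.weights.max() - self.weights.min())
        degenerate = w_range < 1e-9 * float(self.weights.mean())
        if degenerate:
            theta = theta0
            converged = False
            nfev = 0
        else:
            sol = least_squares(
                resid,
                theta0,
                args=(self.times, self.weights),
                bounds=(lo, hi),
                method="trf",
                x_scale="jac",
                ftol=1e-12,
                xtol=1e-12,
                gtol=1e-12,
                max_nfev=max_nfev,
            )
            theta = sol.x
            converged = bool(sol.status > 0)
            nfev = sol.nfev

        if self.model_tag == "g1":
            params: G1Params | G2Params = G1Params(*theta)
            derived = derive_from_g1(params, t_slaughter=t_slaughter)
            fitted = np.asarray(predict_g1(params, self.times))
        else:
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # negative lam already allowed
                params = G2Params(*theta)
            derived = derive_from_g2(params, t_slaughter=t_slaughter)
            fitted = np.asarray(predict_g2(params, self.times))

        rss = float(np.sum((fitted - self.weights) ** 2))
        return GompertzResults(
            model=self,
            model_tag=self.model_tag,
            params=params,
            derived=derived,
            rss=rss,
            n_obs=int(self.times.size),
            converged=converged,
            fitted_weights=fitted,
            nfev=nfev,
        )


@dataclass
class GompertzResults:
    """Estimates, derived traits and goodness of fit for one bird."""

    model: GompertzModel
    model_tag: str
    params: G1Params | G2Params
    derived: DerivedTraits
    rss: float
    n_obs: int
    converged: bool
    fitted_weights: np.ndarray
    nfev: int = 0
    n_params: int = N_PARAMS

    @property
    def tss(self) -> float:
        w = self.model.weights
        return float(np.sum((w - w.mean()) ** 2))

    @property
    def r2(self) -> float:
        tss = self.tss
        return float("nan") if tss == 0 else 1.0 - self.rss / tss

    @property
    def r2_adj(self) -> float:
        """Adjusted r2; NaN when there are too few residual df to adjust."""
        n, p = self.n_obs, self.n_params
        if n - p - 1 <= 0:
            return float("nan")
        return 1.0 - (1.0 - self.r2) * (n - 1) / (n - p - 1)

    @property
    def aic(self) -> float:
        """n*ln(RSS/n) + 2*(p+1), the residual variance counted as a parameter.

        A perfect fit returns -inf as a sentinel.
        """
        if self.rss <= 0.0:
            return float("-inf")
        return self.n_obs * float(np.log(self.rss / self.n_obs)) + 2 * (self.n_params + 1)

    def to_dict(self) -> dict:
        d = {
            "model": self.model_tag,
            "bwa": self.params.bwa,
            "bwip": self.derived.bwip,
            "tip": self.derived.tip,
            "mgr": self.derived.mgr,
            "bws": self.derived.bws,
            "dm": self.derived.dm,
            "rss": self.rss,
            "n_obs": self.n_obs,
            "r2_adj": self.r2_adj,
            "aic": self.aic,
            "converged": self.converged,
        }
        if isinstance(self.params, G1Params):
            d["b"] = self.params.b
            d["k"] = self.params.k
        else:
            d["mu"] = self.params.mu
            d["lam"] = self.params.lam
        d.update(self.model.labels)
        return d

    def summary(self) -> str:
        lines = [
            f"Gompertz fit ({self.model_tag.upper()})",
            "-" * 40,
        ]
        for key, val in self.model.labels.items():
            lines.append(f"{key:>12}: {val}")
        if isinstance(self.params, G1Params):
            lines += [
                f"{'BWa (g)':>12}: {self.params.bwa:10.1f}",
                f"{'b':>12}: {self.params.b:10.3f}",
                f"{'k (1/d)':>12}: {self.params.k:10.4f}",
            ]
        else:
            lines += [
                f"{'BWa (g)':>12}: {self.params.bwa:10.1f}",
                f"{'mu (g/d)':>12}: {self.params.mu:10.2f}",
                f"{'lam (d)':>12}: {self.params.lam:10.2f}",
            ]
        d = self.derived
        lines += [
            f"{'BWip (g)':>12}: {d.bwip:10.1f}",
            f"{'Tip (d)':>12}: {d.tip:10.1f}",
            f"{'MGR (g/d)':>12}: {d.mgr:10.2f}",
            f"{'BWs (g)':>12}: {d.bws:10.1f}",
            f"{'Dm':>12}: {d.dm:10.3f}",
            f"{'r2_adj':>12}: {self.r2_adj:10.5f}",
            f"{'AIC':>12}: {self.aic:10.2f}",
            f"{'converged':>12}: {self.converged}",
        ]
        return "\n".join(lines)


def fit_trajectory(
    trajectory: Trajectory,
    model: str = "g1",
    init: G1Params | G2Params | None = None,
    t_slaughter: float = DEFAULT_SLAUGHTER_AGE,
) -> GompertzResults:
    """Fit one labelled trajectory (requires >= 5 observations)."""
    return GompertzModel.from_trajectory(trajectory, model=model).fit(
        init=init, t_slaughter=t_slaughter
    )


def fit_flock(
    trajectories: Iterable[Trajectory],
    model: str = "g1",
    t_slaughter: float = DEFAULT_SLAUGHTER_AGE,
) -> tuple[list[GompertzResults], pd.DataFrame]:
    """Fit every bird; return results plus a tidy per-bird parameter table."""
    results = [fit_trajectory(tr, model=model, t_slaughter=t_slaughter) for tr in trajectories]
    table = pd.DataFrame([r.to_dict() for r in results])
    return results, table


def goodness(fit: GompertzResults) -> dict[str, float]:
    """Goodness of fit {r2_adj, aic}; raises if r2_adj is undefined."""
    if not fit.converged:
        raise ValueError("goodness of fit requires a converged fit")
    if fit.n_obs - fit.n_params - 1 <= 0:
        raise ValueError(
            f"adjusted r2 undefined with n_obs={fit.n_obs} and {fit.n_params} parameters"
        )
    return {"r2_adj": fit.r2_adj, "aic": fit.aic}


def weekly_correlation(actual, fitted) -> np.ndarray:
    """Pearson correlation between actual and fitted weights per column (age).

    Inputs are bird-by-age matrices of matching shape.  Columns with zero
    variance in either matrix (e.g. identical hatch weights) yield NaN, the
    undefined marker, rather than an exception.
    """
    a = np.asarray(actual, dtype=float)
    f = np.asarray(fitted, dtype=float)
    if a.shape != f.shape or a.ndim != 2:
        raise ValueError(f"shape mismatch: {a.shape} vs {f.shape}")
    out = np.full(a.shape[1], np.nan)
    for j in range(a.shape[1]):
        x, y = a[:, j], f[:, j]
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        out[j] = stats.pearsonr(x, y).statistic
    return out


_CORR_COLS_G1 = ["bwa", "b", "k", "bwip", "tip", "mgr", "bws", "dm"]
_CORR_COLS_G2 = ["bwa", "mu", "lam", "bwip", "tip", "mgr", "bws", "dm"]


def parameter_correlations(fits: Sequence[GompertzResults]) -> pd.DataFrame:
    """Pearson correlation matrix over direct and derived parameters.

    Note the BWip row: BWip is BWa times the Gompertz constant, so its
    correlation with BWa is identically 1.
    """
    fits = [f for f in fits if f.converged]
    if len(fits) < 3:
        raise ValueError("need at least 3 converged fits")
    tags = {f.model_tag for f in fits}
    if len(tags) != 1:
        raise ValueError("all fits must share one parameterization")
    cols = _CORR_COLS_G1 if tags == {"g1"} else _CORR_COLS_G2
    df = pd.DataFrame([f.to_dict() for f in fits])[cols]
    return df.corr()
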