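"""Weighted least-squares fitting of NMRD profiles.

``NMRDFitter`` is a scikit-learn style estimator: construct it with the
free/fixed parameter partition, call ``fit(frequencies, r1)``, read the
fitted parameters from trailing-underscore attributes, and ``predict``
relaxivities on new frequency grids. Positive parameters are optimised
on a log scale and the order parameter S² on a logit scale, so box
bounds are respected smoothly; the objective is multi-modal in the
electron-spin parameters, hence seeded multi-start initialisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .relaxation import NMRDProfile, RelaxationModel, total_r1_profile

__all__ = ["NMRDFitter", "FitResult", "fit_nmrd", "scan_q_ss",
           "compare_profiles", "DEFAULT_BOUNDS", "FREE_PARAMETER_NAMES"]

FREE_PARAMETER_NAMES = ("tau_rl", "tau_m_ss", "s2", "delta2", "tau_v", "q_ss")

#: default box bounds per fittable parameter (SI units; q_ss is a count)
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "tau_rl": (1.0e-12, 1.0e-8),
    "tau_m_ss": (1.0e-11, 1.0e-6),
    "s2": (1.0e-4, 1.0 - 1.0e-4),
    "delta2": (1.0e17, 1.0e21),
    "tau_v": (1.0e-13, 1.0e-9),
    "q_ss": (0.05, 10.0),
}

_RSS_AGREE_RTOL = 1.0e-3  # starts "agree" when within 0.1 % in residual


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class FitResult:
    """Outcome of an NMRD fit."""

    fitted_values: Dict[str, float]
    residual_sum_squares: float
    converged: bool
    n_starts_agreeing: int
    model: RelaxationModel
    bootstrap_ci: Optional[Dict[str, Tuple[float, float]]] = None
    flags: Dict[str, bool] = field(default_factory=dict)


class NMRDFitter(BaseEstimator, RegressorMixin):
    """Fit a second-sphere + outer-sphere relaxivity model to an NMRD
    profile by weighted least squares.

    Parameters
    ----------
    free : names of adjustable parameters, subset of
        ``FREE_PARAMETER_NAMES``. Default mirrors the usual analysis:
        local rotation, second-sphere residence time and order parameter.
    model : RelaxationModel carrying every fixed parameter (and the
        generating values of the free ones, which are ignored as such).
    bounds : optional per-parameter ``(lo, hi)`` overrides.
    n_starts : number of multi-start initialisations (log-uniform within
        bounds; the same seed stream prefix is shared by any two fitters
        with equal ``random_state``, so more starts can only improve the
        returned minimum).
    n_bootstrap : residual-resampling bootstrap replicates for
        percentile confidence intervals (0 disables).
    tol : relative tolerance on residual change (``ftol``).
    random_state : seed for start draws and bootstrap resampling.

    Attributes (after ``fit``)
    --------------------------
    params_ : dict of fitted free-parameter values.
    model_ : RelaxationModel with fitted values substituted.
    rss_ : weighted residual sum of squares.
    converged_ : True when at least one start converged.
    n_starts_agreeing_ : starts within 0.1 % residual of the best.
    bootstrap_ci_ : per-parameter (lo, hi) percentile intervals or None.
    flags_ : diagnostic flags (e.g. ``identifiability_warning``).
    """

    def __init__(self, free: Sequence[str] = ("tau_rl", "tau_m_ss", "s2"),
                 model: Optional[RelaxationModel] = None,
                 bounds: Optional[Dict[str, Tuple[float, float]]] = None,
                 n_starts: int = 8, n_bootstrap: int = 0,
                 ci_level: float = 0.90, tol: float = 1.0e-10,
                 random_state: int = 0):
        self.free = free
        self.model = model
        self.bounds = bounds
        self.n_starts = n_starts
        self.n_bootstrap = n_bootstrap
        self.ci_level = ci_level
        self.tol = tol
        self.random_state = random_state

    # -- parameter transforms ------------------------------------------------

    def _bounds_for(self, name: str) -> Tuple[float, float]:
        if self.bounds and name in self.bounds:
            lo, hi = self.bounds[name]
        else:
            lo, hi = DEFAULT_BOUNDS[name]
        if not (0 < lo < hi):
            raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
        return lo, hi

    def _to_internal(self, name: str, value: float) -> float:
        return _logit(value) if name == "s2" else np.log(value)

    def _from_internal(self, name: str, x: float) -> float:
        return float(_expit(x)) if name == "s2" else float(np.exp(x))

    # -- fitting -------------------------------------------------------------

    def fit(self, X, y, y_err=None):
        """Fit to frequencies ``X`` (MHz) and relaxivities ``y``.

        ``y_err`` gives per-point standard errors; weights are 1/err²,
        or unity when absent.
        """
        freqs = np.asarray(X, dtype=float).ravel()
        r1 = np.asarray(y, dtype=float).ravel()
        if freqs.shape != r1.shape:
            raise ValueError("X and y must have equal length")
        order = np.argsort(freqs)  # row order must not matter
        freqs, r1 = freqs[order], r1[order]
        if y_err is not None:
            y_err = np.asarray(y_err, dtype=float).ravel()[order]
        free = tuple(self.free)
        unknown = set(free) - set(FREE_PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"unknown free parameters: {sorted(unknown)}")
        if len(set(free)) != len(free):
            raise ValueError("duplicate free parameter names")
        if freqs.size < 2 * len(free):
            raise ValueError("need at least twice as many points as free "
                             "parameters")
        base = self.model if self.model is not None else RelaxationModel()
        weights = (np.ones_like(r1) if y_err is None
                   else 1.0 / np.asarray(y_err, float) ** 2)
        sqrt_w = np.sqrt(weights)

        self.flags_ = {}
        if np.ptp(r1) < 1.0e-12 * np.abs(r1).max():
            warnings.warn("profile is constant in frequency; free "
                          "parameters are unlikely to be identifiable",
                          UserWarning)
            self.flags_["identifiability_warning"] = True

        lo = np.array([self._to_internal(n, self._bounds_for(n)[0]) for n in free])
        hi = np.array([self._to_internal(n, self._bounds_for(n)[1]) for n in free])

        def residuals(x):
            values = {n: self._from_internal(n, xi) for n, xi in zip(free, x)}
            m = base.replace(**values)
            pred = total_r1_profile(freqs, m).r1
            return sqrt_w * (pred - r1)

        rng = np.random.default_rng(self.random_state)
        starts = rng.uniform(lo, hi, size=(max(1, self.n_starts), len(free)))

        solutions = []
        for x0 in starts:
            try:
                sol = least_squares(residuals, x0, bounds=(lo, hi),
                                    method="trf", ftol=self.tol,
                                    xtol=1.0e-12, gtol=1.0e-12,
                                    max_nfev=5000)
            except Exception:  # pragma: no cover - defensive
                continue
            if sol.success:
                solutions.append(sol)
        if not solutions:
            self.converged_ = False
            self.params_ = {}
            self.rss_ = np.inf
            self.n_starts_agreeing_ = 0
            self.model_ = base
            self.bootstrap_ci_ = None
            warnings.warn("no multi-start converged", UserWarning)
            return self

        rss = np.array([2.0 * s.cost for s in solutions])
        best = solutions[int(np.argmin(rss))]
        best_rss = float(2.0 * best.cost)
        agree_tol = _RSS_AGREE_RTOL * max(best_rss, 1.0e-300)
        self.n_starts_agreeing_ = int(np.sum(rss <= best_rss + agree_tol))
        self.converged_ = True
        self.params_ = {n: self._from_internal(n, xi)
                        for n, xi in zip(free, best.x)}
        self.model_ = base.replace(**self.params_)
        self.rss_ = best_rss
        self._x_internal_ = best.x
        self._free_ = free
        self._freqs_ = freqs
        self._sqrt_w_ = sqrt_w
        self.bootstrap_ci_ = (self._bootstrap(residuals, r1, rng)
                              if self.n_bootstrap > 0 else None)
        return self

    def _bootstrap(self, residuals, r1, rng):
        """Percentile CIs from residual resampling on the fixed design."""
        pred = residuals(self._x_internal_) / self._sqrt_w_ + r1
        resid = r1 - pred
        lo = np.array([self._to_internal(n, self._bounds_for(n)[0])
                       for n in self._free_])
        hi = np.array([self._to_internal(n, self._bounds_for(n)[1])
                       for n in self._free_])
        draws = np.empty((self.n_bootstrap, len(self._free_)))
        for b in range(self.n_bootstrap):
            y_star = pred + rng.choice(resid, size=resid.size, replace=True)

            def res_b(x, y_star=y_star):
                values = {n: self._from_internal(n, xi)
                          for n, xi in zip(self._free_, x)}
                m = (self.model or RelaxationModel()).replace(**values)
                return self._sqrt_w_ * (
                    total_r1_profile(self._freqs_, m).r1 - y_star)

            sol = least_squares(res_b, self._x_internal_, bounds=(lo, hi),
                                method="trf", ftol=1.0e-8)
            draws[b] = sol.x
        alpha = 0.5 * (1.0 - self.ci_level)
        ci = {}
        for j, name in enumerate(self._free_):
            qlo, qhi = np.quantile(draws[:, j], [alpha, 1.0 - alpha])
            ci[name] = (self._from_internal(name, qlo),
                        self._from_internal(name, qhi))
        return ci

    def predict(self, X):
        """Model relaxivities at frequencies ``X`` (MHz)."""
        freqs = np.asarray(X, dtype=float).ravel()
        return total_r1_profile(np.sort(freqs), self.model_).r1[
            np.argsort(np.argsort(freqs))]

    def result_(self) -> FitResult:
        """Bundle fitted attributes into a ``FitResult``."""
        return FitResult(fitted_values=dict(self.params_),
                         residual_sum_squares=self.rss_,
                         converged=self.converged_,
                         n_starts_agreeing=self.n_starts_agreeing_,
                         model=self.model_,
                         bootstrap_ci=self.bootstrap_ci_,
                         flags=dict(self.flags_))


def fit_nmrd(profile: NMRDProfile,
             free: Sequence[str] = ("tau_rl", "tau_m_ss", "s2"),
             model: Optional[RelaxationModel] = None,
             bounds: Optional[Dict[str, Tuple[float, float]]] = None,
             n_starts: int = 8, n_bootstrap: int = 0,
             seed: int = 0) -> FitResult:
    """Functional wrapper over :class:`NMRDFitter`."""
    est = NMRDFitter(free=free, model=model, bounds=bounds,
                     n_starts=n_starts, n_bootstrap=n_bootstrap,
                     random_state=seed)
    est.fit(profile.frequencies, profile.r1, y_err=profile.r1_err)
    return est.result_()


def scan_q_ss(profile: NMRDProfile, q_candidates: Sequence[float],
              free: Sequence[str] = ("tau_rl", "tau_m_ss", "s2"),
              model: Optional[RelaxationModel] = None,
              n_starts: int = 8, seed: int = 0):
    """Fit once per candidate second-sphere water count (held fixed);
    return ``(q, FitResult)`` pairs sorted by residual, best first."""
    cands = list(q_candidates)
    if not cands or any(q < 0 for q in cands):
        raise ValueError("q_candidates must be non-empty, non-negative")
    base = model if model is not None else RelaxationModel()
    results = []
    for q in cands:
        res = fit_nmrd(profile, free=free, model=base.replace(q_ss=float(q)),
                       n_starts=n_starts, seed=seed)
        results.append((q, res))
    results.sort(key=lambda t: t[1].residual_sum_squares)
    return results


def compare_profiles(p1: NMRDProfile, p2: NMRDProfile,
                     symmetry_tol: float = 0.01):
    """Mean and max relative difference between two profiles.

    Profiles on different grids are linearly interpolated in
    log-frequency onto the coarser grid restricted to the overlapping
    frequency range. Differences are normalised by the reference (p1)
    values; ``symmetric`` is False when swapping the reference moves
    either statistic by more than ``symmetry_tol``.
    """
    f1, f2 = p1.frequencies, p2.frequencies
    lo = max(f1.min(), f2.min())
    hi = min(f1.max(), f2.max())
    if lo >= hi and not np.array_equal(f1, f2):
        raise ValueError("profiles have no overlapping frequency range")
    if np.array_equal(f1, f2):
        grid, r1a, r1b = f1, p1.r1, p2.r1
    else:
        coarse = f1 if f1.size <= f2.size else f2
        grid = coarse[(coarse >= lo) & (coarse <= hi)]
        if grid.size == 0:
            raise ValueError("profiles have no overlapping frequency range")
        r1a = np.interp(np.log(grid), np.log(f1), p1.r1)
        r1b = np.interp(np.log(grid), np.log(f2), p2.r1)

    def stats(ref, other):
        rel = np.abs(ref - other) / np.abs(ref)
        return float(np.mean(rel)), float(np.max(rel))

    mean_fwd, max_fwd = stats(r1a, r1b)
    mean_rev, max_rev = stats(r1b, r1a)
    symmetric = (abs(mean_fwd - mean_rev) <= symmetry_tol
                 and abs(max_fwd - max_rev) <= symmetry_tol)
    return {"mean_rel_diff": mean_fwd, "max_rel_diff": max_fwd,
            "symmetric": symmetric, "n_points": int(grid.size)}
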