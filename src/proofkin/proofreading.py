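"""Kinetic proofreading: model, fit, and half-life/occupancy analyses.

After a ligand binds the receptor, the receptor must traverse ``n``
irreversible intermediate steps before it signals productively.  The steps
proceed only while the ligand remains bound and reset on dissociation, so each
step is a kinetic race between the forward transition (rate ``kp = ln2/tau_p``)
and ligand dissociation (rate ``koff = ln2/tau_off``).  The per-step success
probability is

    alpha = kp / (kp + koff) = tau_off / (tau_off + tau_p)

and a fraction ``alpha**n`` of bound receptors completes the chain.  Under the
strong-proofreading assumption (``tau_p >> tau_off``, so ``alpha`` is
proportional to ``tau_off``), the amount of productive upstream signal from
``R`` bound receptors scales as ``R * tau_off**n``, and the downstream DAG
response is modeled as saturable:

    DAG = A * R*tau**n / (K + R*tau**n) + beta

where ``K`` is the upstream signal giving half-maximal DAG, ``beta`` is basal
signaling and ``A`` a free amplitude absorbing the arbitrary reporter units.
Fitting ``(n, K, beta, A)`` to single-cell (occupancy, half-life, DAG)
measurements yields ``n``, the degree of proofreading, with a normal-theory
95% confidence interval.  Because occupancy is recorded in arbitrary units that
drift between imaging days, fits are performed per day and never pooled unless
explicitly requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import FitConvergenceError

__all__ = [
    "StepParams",
    "ProofreadingFit",
    "KineticProofreadingRegressor",
    "NadarayaWatsonRegressor",
    "completion_probability",
    "dag_response",
    "fit_proofreading_model",
    "amplification_factor",
    "occupancy_gated_correlation",
    "kernel_smooth",
]

_N_BOUNDS = (0.0, 10.0)


@dataclass(frozen=True)
class StepParams:
    """Forward proofreading-step half-life and number of steps."""

    tau_p: float
    n_steps: int

    def __post_init__(self) -> None:
        if not self.tau_p > 0:
            raise ValueError("tau_p must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")


@dataclass(frozen=True)
class ProofreadingFit:
    """Fitted saturable proofreading response for one day group."""

    n: float
    K: float
    beta: float
    amplitude: float
    covariance: np.ndarray  # 4x4 over (n, K, beta, amplitude)
    ci95_n: tuple[float, float]
    dof: int
    rss: float
    normalization_scheme: str
    days_included: tuple[str, ...]
    n_at_bound: bool = False

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "K": self.K,
            "beta": self.beta,
            "amplitude": self.amplitude,
            "covariance": np.asarray(self.covariance).tolist(),
            "ci95_n": list(self.ci95_n),
            "dof": self.dof,
            "rss": self.rss,
            "normalization_scheme": self.normalization_scheme,
            "days_included": list(self.days_included),
            "n_at_bound": self.n_at_bound,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProofreadingFit":
        return cls(
            n=d["n"],
            K=d["K"],
            beta=d["beta"],
            amplitude=d["amplitude"],
            covariance=np.asarray(d["covariance"], dtype=float),
            ci95_n=tuple(d["ci95_n"]),
            dof=int(d["dof"]),
            rss=d["rss"],
            normalization_scheme=d["normalization_scheme"],
            days_included=tuple(d["days_included"]),
            n_at_bound=bool(d.get("n_at_bound", False)),
        )


def completion_probability(tau_off: float | np.ndarray, step: StepParams) -> float | np.ndarray:
    """Probability that a bound receptor completes all proofreading steps.

    ``alpha**n`` with ``alpha = tau_off / (tau_off + tau_p)``; monotone
    increasing in ``tau_off``, decreasing in ``tau_p`` and ``n_steps``.
    """
    tau = np.asarray(tau_off, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau_off must be positive")
    alpha = tau / (tau + step.tau_p)
    out = alpha**step.n_steps
    return float(out) if np.ndim(tau_off) == 0 else out


def dag_response(R, tau_off, n: float, K: float, beta: float, amplitude: float):
    """Saturable DAG response ``A * R*tau**n / (K + R*tau**n) + beta``."""
    if not K > 0:
        raise ValueError("K must be positive")
    R = np.asarray(R, dtype=float)
    tau = np.asarray(tau_off, dtype=float)
    signal = R * tau**n
    out = amplitude * signal / (K + signal) + beta
    return float(out) if out.ndim == 0 else out


def amplification_factor(n: float, fold_halflife: float, include_occupancy: bool = False) -> float:
    """Fold change in DAG for a fold change in binding half-life, far from saturation.

    With occupancy held fixed, DAG is proportional to ``tau**n`` when
    ``R*tau**n << K``, so a ``fold_halflife``-fold half-life change yields a
    ``fold_halflife**n``-fold DAG change.  With ``include_occupancy=True`` the
    occupancy change that a longer-lived ligand also produces (``R``
    proportional to ``tau`` far from binding saturation) is counted too, giving
    ``fold_halflife**(n + 1)`` — the relevant figure when comparing two ligands
    at equal density, e.g. a self- versus foreign-peptide scenario.
    """
    if not fold_halflife > 0:
        raise ValueError("fold_halflife must be positive")
    exponent = n + 1.0 if include_occupancy else float(n)
    return float(fold_halflife) ** exponent


class KineticProofreadingRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of the saturable proofreading response.

    ``X`` has two columns, ``(occupancy, half_life)``; ``y`` is the DAG level.
    Fitted by bounded trust-region least squares with ``n`` in ``[0, 10]``,
    ``K, A > 0`` and ``beta >= 0``.

    Parameters
    ----------
    ci_method : {'bootstrap', 'linear'}, default 'bootstrap'
        How ``var(n)`` in the 95% CI ``n +- 1.96*sqrt(var(n))`` is estimated:
        the spread of ``n`` over case-resampling bootstrap refits (default;
        calibrated even when the least-squares surface is curved along the
        correlated n-K ridge), or the linearized fit covariance (the
        conventional normal-theory estimate).
    n_bootstrap : int
        Number of bootstrap resamples for ``ci_method='bootstrap'``.
    random_state : int
        Seed for the bootstrap resampler.

    Attributes
    ----------
    n_, K_, beta_, amplitude_ : float
        Fitted parameters.
    covariance_ : ndarray (4, 4)
        Linearized covariance of ``(n, K, beta, amplitude)`` from the Jacobian
        at the solution, scaled by ``rss / dof``.
    n_stderr_ : float
        Standard error of ``n`` per ``ci_method``.
    ci95_n_ : tuple (low, high)
        ``n +- 1.96 * n_stderr_`` (normal approximation; requires the degrees
        of freedom to be well in excess of 30 to be trustworthy).
    dof_ : int
    rss_ : float
    n_at_bound_ : bool
        True when the fitted ``n`` landed on a box bound.
    """

    def __init__(
        self,
        n_bounds: tuple[float, float] = _N_BOUNDS,
        max_nfev: int = 20000,
        min_dof: int = 5,
        ci_method: str = "bootstrap",
        n_bootstrap: int = 200,
        random_state: int = 0,
    ):
        self.n_bounds = n_bounds
        self.max_nfev = max_nfev
        self.min_dof = min_dof
        self.ci_method = ci_method
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: (occupancy, half_life)")
        if X.shape[0] != y.size:
            raise ValueError("X and y must have the same number of rows")
        if np.any(X[:, 1] <= 0):
            raise ValueError("half-lives must be positive")
        dof = y.size - 4
        if dof <= self.min_dof - 1:
            raise ValueError(f"degrees of freedom {dof} too small (need > {self.min_dof - 1})")

        if self.ci_method not in ("linear", "bootstrap"):
            raise ValueError(f"unknown ci_method {self.ci_method!r}")

        R, tau = X[:, 0], X[:, 1]
        sol = self._solve(R, tau, y)
        self.n_, self.K_, self.beta_, self.amplitude_ = map(float, sol.x)
        self.rss_ = float(2.0 * sol.cost)
        self.dof_ = int(dof)
        self.covariance_ = self._covariance(sol.jac)
        if self.ci_method == "bootstrap":
            self.n_stderr_ = self._bootstrap_stderr(R, tau, y, sol.x)
        else:
            self.n_stderr_ = float(np.sqrt(max(self.covariance_[0, 0], 0.0)))
        self.ci95_n_ = (self.n_ - 1.96 * self.n_stderr_, self.n_ + 1.96 * self.n_stderr_)
        tol = 1e-8 * max(1.0, self.n_bounds[1])
        self.n_at_bound_ = (
            abs(self.n_ - self.n_bounds[0]) < tol or abs(self.n_ - self.n_bounds[1]) < tol
        )
        return self

    def _solve(self, R, tau, y, p0=None, tol=1e-14):
        if p0 is None:
            beta0 = float(np.min(y))
            amp0 = max(float(np.max(y)) - beta0, 1e-6)
            K0 = max(float(np.median(R * tau)), 1e-6)
            p0 = np.array([1.0, K0, max(beta0, 0.0), amp0])
        lo = np.array([self.n_bounds[0], 1e-12, 0.0, 1e-12])
        hi = np.array([self.n_bounds[1], np.inf, np.inf, np.inf])
        p0 = np.clip(p0, lo + 1e-9, None)

        def resid(p):
            n, K, beta, A = p
            return dag_response(R, tau, n, K, beta, A) - y

        sol = least_squares(
            resid,
            p0,
            bounds=(lo, hi),
            method="trf",
            x_scale="jac",
            xtol=tol,
            ftol=tol,
            gtol=tol,
            max_nfev=self.max_nfev,
        )
        if not sol.success:
            raise FitConvergenceError(
                f"proofreading fit did not converge: {sol.message} (status {sol.status})"
            )
        return sol

    def _bootstrap_stderr(self, R, tau, y, p_hat) -> float:
        """Case-resampling bootstrap standard error of ``n``.

        The linearized covariance understates the uncertainty of ``n`` when
        the fit surface is curved along the correlated (n, K) ridge, so the
        default CI uses the bootstrap spread of refitted ``n`` values instead.
        Resample fits warm-start from the full-data solution.
        """
        rng = np.random.default_rng(self.random_state)
        m = y.size
        ns = []
        for _ in range(self.n_bootstrap):
            idx = rng.integers(0, m, m)
            try:
                sol = self._solve(R[idx], tau[idx], y[idx], p0=p_hat.copy(), tol=1e-10)
            except FitConvergenceError:
                continue
            ns.append(sol.x[0])
        if len(ns) < max(10, self.n_bootstrap // 4):
            raise FitConvergenceError(
                f"bootstrap resampling converged in only {len(ns)}/{self.n_bootstrap} resamples"
            )
        return float(np.std(ns, ddof=1))

    def _covariance(self, jac: np.ndarray) -> np.ndarray:
        # Column-equilibrate the Jacobian before inverting: K is typically many
        # orders of magnitude larger than n, and an unscaled pinv cutoff makes
        # var(n) depend on the arbitrary units of y.  The pseudoinverse still
        # tolerates directions that are truly degenerate (e.g. n at a bound).
        norms = np.linalg.norm(jac, axis=0)
        norms[norms == 0] = 1.0
        js = jac / norms
        cov_s = np.linalg.pinv(js.T @ js, rcond=1e-10)
        cov = (cov_s / np.outer(norms, norms)) * (self.rss_ / max(self.dof_, 1))
        return 0.5 * (cov + cov.T)

    def predict(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        return dag_response(X[:, 0], X[:, 1], self.n_, self.K_, self.beta_, self.amplitude_)


def _saturation_reference(dag: np.ndarray) -> float:
    """Reference DAG for the 'saturation' normalization: mean of the top decile."""
    q90 = np.quantile(dag, 0.9)
    return float(np.mean(dag[dag >= q90]))


def _normalize(dag: np.ndarray, scheme: str, reference: float | None) -> np.ndarray:
    if scheme == "none":
        return dag
    if scheme == "saturation":
        ref = reference if reference is not None else _saturation_reference(dag)
    elif scheme == "pp2":
        if reference is None:
            raise ValueError("pp2 normalization requires a reference value")
        ref = reference
    else:
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    if not ref > 0:
        raise ValueError(f"normalization reference must be positive, got {ref}")
    return dag / ref


def fit_proofreading_model(
    cells: pd.DataFrame,
    normalization: str = "saturation",
    group_by_day: bool = True,
    references: dict | None = None,
    allow_pooling: bool = False,
    ci_method: str = "bootstrap",
    random_state: int = 0,
) -> dict[str, ProofreadingFit]:
    """Fit the saturable proofreading response per day group.

    Parameters
    ----------
    cells : DataFrame
        Needs columns ``day_id``, ``occupancy_au``, ``half_life_s``,
        ``dag_au``.  Datasets (ligand densities) within a day are combined.
    normalization : {'saturation', 'pp2', 'none'}
        DAG rescaling applied per group before fitting.  Rescaling ``y`` does
        not change the fitted ``n``; it standardizes the reported amplitude.
    references : dict, optional
        Per-group normalization reference values (required for 'pp2').
    group_by_day : bool
        Occupancy arbitrary units are only comparable within one imaging day,
        so fits are grouped by ``day_id``.  Pooling across days requires
        ``group_by_day=False`` together with ``allow_pooling=True``.

    Returns
    -------
    dict mapping group label to :class:`ProofreadingFit`.
    """
    required = {"day_id", "occupancy_au", "half_life_s", "dag_au"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    if not group_by_day:
        if not allow_pooling:
            raise ValueError(
                "pooling across days mixes incompatible occupancy units; "
                "pass allow_pooling=True to override"
            )
        groups = [("pooled", cells)]
    else:
        groups = list(cells.groupby("day_id", sort=True))

    fits: dict[str, ProofreadingFit] = {}
    for day, sub in groups:
        day = str(day)
        dag = sub["dag_au"].to_numpy(dtype=float)
        ref = references.get(day) if references else None
        y = _normalize(dag, normalization, ref)
        X = sub[["occupancy_au", "half_life_s"]].to_numpy(dtype=float)
        est = KineticProofreadingRegressor(ci_method=ci_method, random_state=random_state).fit(
            X, y
        )
        fits[day] = ProofreadingFit(
            n=est.n_,
            K=est.K_,
            beta=est.beta_,
            amplitude=est.amplitude_,
            covariance=est.covariance_,
            ci95_n=est.ci95_n_,
            dof=est.dof_,
            rss=est.rss_,
            normalization_scheme=normalization,
            days_included=(day,) if day != "pooled" else tuple(map(str, cells["day_id"].unique())),
            n_at_bound=est.n_at_bound_,
        )
    return fits


def occupancy_gated_correlation(
    cells: pd.DataFrame, occupancy_band: tuple[float, float] | None = None
) -> tuple[float, int]:
    """Spearman correlation of DAG with half-life inside an occupancy gate.

    Gating to a narrow occupancy band isolates the effect of binding half-life
    from that of receptor occupancy.  ``occupancy_band`` is an absolute
    ``(low, high)`` interval; when None, the central band between the 40th and
    60th occupancy percentiles is used.

    Returns ``(spearman_rho, n_cells)``.
    """
    occ = cells["occupancy_au"].to_numpy(dtype=float)
    if occupancy_band is None:
        occupancy_band = (float(np.quantile(occ, 0.4)), float(np.quantile(occ, 0.6)))
    low, high = occupancy_band
    mask = (occ >= low) & (occ <= high)
    if not mask.any():
        raise ValueError(f"occupancy gate ({low}, {high}) selects no cells")
    sub = cells.loc[mask]
    n_cells = int(mask.sum())
    if n_cells < 3:
        raise ValueError(f"only {n_cells} cells in gate; need >= 3 for a rank correlation")
    tau = sub["half_life_s"].to_numpy(dtype=float)
    dag = sub["dag_au"].to_numpy(dtype=float)
    if np.ptp(tau) == 0 or np.ptp(dag) == 0:
        raise ValueError("constant half-life or DAG inside the gate; correlation undefined")
    rho = stats.spearmanr(tau, dag).statistic
    return float(rho), n_cells


class NadarayaWatsonRegressor(RegressorMixin, BaseEstimator):
    """Nadaraya-Watson kernel-smoothing regression with a Gaussian kernel.

    The fitted value at ``x0`` is the kernel-weighted mean of the observed
    ``y``, so predictions are convex combinations of the data (always within
    ``[min(y), max(y)]``).  Grid points farther than ~8 bandwidths from every
    observation receive zero total weight and are returned as NaN.
    """

    def __init__(self, bandwidth: float = 1.0):
        self.bandwidth = bandwidth

    def fit(self, X, y):
        if not self.bandwidth > 0:
            raise ValueError("bandwidth must be positive")
        self.X_ = np.asarray(X, dtype=float).reshape(-1)
        self.y_ = np.asarray(y, dtype=float).reshape(-1)
        if self.X_.size != self.y_.size:
            raise ValueError("X and y must have the same length")
        if self.X_.size == 0:
            raise ValueError("no data")
        return self

    def predict(self, X):
        check_is_fitted(self)
        grid = np.asarray(X, dtype=float).reshape(-1)
        z = (grid[:, None] - self.X_[None, :]) / self.bandwidth
        # subtract the row-max exponent for numerical stability at far points
        zmax = -0.5 * np.min(z**2, axis=1, keepdims=True)
        w = np.exp(-0.5 * z**2 - zmax)
        tot = w.sum(axis=1)
        out = np.full(grid.shape, np.nan)
        # points beyond ~8 bandwidths of all data have no meaningful support
        near = np.min(np.abs(z), axis=1) <= 8.0
        valid = near & (tot > 0)
        out[valid] = (w[valid] @ self.y_) / tot[valid]
        return out


def kernel_smooth(
    x, y, bandwidth: float, grid=None, n_grid: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel smoothed curve of ``y`` against ``x`` on a grid.

    Returns ``(grid, fitted)``; grid points with no kernel support are NaN.
    """
    est = NadarayaWatsonRegressor(bandwidth=bandwidth).fit(x, y)
    if grid is None:
        grid = np.linspace(float(np.min(est.X_)), float(np.max(est.X_)), n_grid)
    grid = np.asarray(grid, dtype=float)
    return grid, est.predict(grid)
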