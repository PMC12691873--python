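"""Cox proportional-hazards model: partial likelihood, fitting, diagnostics.

The engine maximizes the log partial likelihood by Newton--Raphson with
step-halving, supporting Efron (default) and Breslow tie corrections and an
optional quadratic (ridge) penalty on a subset of coefficients -- the same
machinery drives both the fixed-effects model and the penalized
random-intercept model.  Risk-set sums are organized so that the score and
the observed information reduce to suffix cumulative sums plus two dense
matrix products, which keeps fits with hundreds of columns and tens of
thousands of rows fast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "Dataset",
    "CovariateSpec",
    "CoxFit",
    "encode_design",
    "fit_cox",
    "hazard_ratios",
    "schoenfeld_ph_test",
    "vif",
    "breslow_baseline",
    "MonotoneLikelihoodWarning",
]


class MonotoneLikelihoodWarning(UserWarning):
    """A coefficient appears to diverge (monotone partial likelihood)."""


@dataclass
class Dataset:
    """Patient-level survival table.

    ``frame`` must contain ``time_months`` (positive, finite), ``event``
    (0/1, 1 = death) and ``region_id`` columns plus covariates.
    """

    frame: pd.DataFrame
    time_col: str = "time_months"
    event_col: str = "event"
    region_col: str = "region_id"

    def __post_init__(self):
        f = self.frame
        for col in (self.time_col, self.event_col, self.region_col):
            if col not in f.columns:
                raise ValueError(f"dataset is missing required column {col!r}")
        t = f[self.time_col].to_numpy(dtype=float)
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("survival times must be positive and finite")
        ev = f[self.event_col].to_numpy()
        if not np.isin(ev, [0, 1]).all():
            raise ValueError("event indicator must be 0/1")

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def n_events(self) -> int:
        return int(self.frame[self.event_col].sum())

    def times(self) -> np.ndarray:
        return self.frame[self.time_col].to_numpy(dtype=float)

    def events(self) -> np.ndarray:
        return self.frame[self.event_col].to_numpy(dtype=float)

    def region_labels(self) -> np.ndarray:
        return self.frame[self.region_col].astype(str).to_numpy()

    @classmethod
    def from_csv(cls, path, **kwargs) -> "Dataset":
        return cls(pd.read_csv(path), **kwargs)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class CovariateSpec:
    """Declaration of one model covariate.

    Categorical covariates are dummy-encoded with the reference level (the
    first of ``levels`` unless given) excluded; continuous covariates pass
    through unchanged.  Column order is deterministic: spec order, then
    level order.
    """

    name: str
    kind: str  # 'categorical' | 'continuous'
    levels: tuple[str, ...] | None = None
    reference: str | None = None
    note: str | None = None

    def __post_init__(self):
        if self.kind not in {"categorical", "continuous"}:
            raise ValueError("kind must be 'categorical' or 'continuous'")
        if self.kind == "categorical":
            if not self.levels:
                raise ValueError(f"categorical covariate {self.name!r} needs levels")
            ref = self.reference if self.reference is not None else self.levels[0]
            if ref not in self.levels:
                raise ValueError(
                    f"reference {ref!r} not among levels of {self.name!r}"
                )
            object.__setattr__(self, "reference", ref)


def encode_design(
    dataset: Dataset, specs: Sequence[CovariateSpec]
) -> tuple[np.ndarray, list[str]]:
    """Design matrix and column names for the given covariate specs.

    Raises on unseen categorical levels and on missing values (no
    imputation is attempted).
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    f = dataset.frame
    for spec in specs:
        if spec.name not in f.columns:
            raise ValueError(f"covariate {spec.name!r} not in dataset")
        raw = f[spec.name]
        if raw.isna().any():
            raise ValueError(
                f"covariate {spec.name!r} has missing values; "
                "impute or drop rows before fitting"
            )
        if spec.kind == "continuous":
            cols.append(raw.to_numpy(dtype=float))
            names.append(spec.name)
        else:
            vals = raw.astype(str).to_numpy()
            unknown = set(vals) - set(spec.levels)
            if unknown:
                raise ValueError(
                    f"unseen level(s) {sorted(unknown)} for covariate {spec.name!r}"
                )
            for lev in spec.levels:
                if lev == spec.reference:
                    continue
                cols.append((vals == lev).astype(float))
                names.append(f"{spec.name}[{lev}]")
    if not cols:
        return np.empty((dataset.n, 0)), []
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# partial-likelihood engine


class PartialLikelihood:
    """Log partial likelihood, score and observed information for fixed data.

    Rows are pre-sorted by ascending time; for each distinct event time the
    risk set is a suffix of the sorted order, so ``S0`` and ``S1`` come from
    reversed cumulative sums.  The ``S2`` part of the information collapses
    to ``X' diag(w * a) X`` where ``a_i`` accumulates inverse risk-set
    denominators over event times up to ``t_i`` (with the Efron within-tie
    adjustment), so the full information is two dense matrix products.
    """

    def __init__(self, times, events, X, ties: str = "efron", offset=None):
        if ties not in {"efron", "breslow"}:
            raise ValueError("ties must be 'efron' or 'breslow'")
        times = np.asarray(times, dtype=float)
        d = np.asarray(events, dtype=float)
        X = np.ascontiguousarray(X, dtype=float)
        n = times.shape[0]
        order = np.argsort(times, kind="stable")
        self.ties = ties
        self.n = n
        self.p = X.shape[1]
        self.X = X[order]
        self.t = times[order]
        self.d = d[order].astype(bool)
        self.offset = (
            np.zeros(n) if offset is None else np.asarray(offset, dtype=float)[order]
        )
        self.order = order
        self.event_pos = np.flatnonzero(self.d)
        if self.event_pos.size == 0:
            raise ValueError("dataset contains no events")
        ev_times = self.t[self.event_pos]
        self.ut = np.unique(ev_times)
        self.G = self.ut.size
        self.risk_start = np.searchsorted(self.t, self.ut, side="left")
        self.g_of_event = np.searchsorted(self.ut, ev_times)
        self.d_g = np.bincount(self.g_of_event, minlength=self.G).astype(float)
        first = np.concatenate([[0], np.cumsum(self.d_g)[:-1]]).astype(int)
        self.l_within = np.arange(self.event_pos.size) - first[self.g_of_event]
        if ties == "efron":
            self.frac = self.l_within / self.d_g[self.g_of_event]
        else:
            self.frac = np.zeros(self.event_pos.size)
        # group index of the last event time <= t_i, +1 (0 = none)
        self.g_upto = np.searchsorted(self.ut, self.t, side="right")

    # -- helpers -----------------------------------------------------------

    def _weights(self, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        eta = self.X @ beta + self.offset
        # guard against overflow during step search
        eta = np.clip(eta, -500, 500)
        return eta, np.exp(eta)

    def _denoms(self, w: np.ndarray):
        S0_suffix = np.cumsum(w[::-1])[::-1]
        S0_g = S0_suffix[self.risk_start]
        if self.ties == "efron":
            W_t = np.bincount(self.g_of_event, weights=w[self.event_pos], minlength=self.G)
            denom = S0_g[self.g_of_event] - self.frac * W_t[self.g_of_event]
        else:
            W_t = None
            denom = S0_g[self.g_of_event]
        return S0_g, W_t, denom

    def loglik(self, beta: np.ndarray) -> float:
        eta, w = self._weights(beta)
        _, _, denom = self._denoms(w)
        return float(eta[self.event_pos].sum() - np.log(denom).sum())

    def loglik_score_info(self, beta: np.ndarray):
        """Return ``(loglik, score, information)`` at ``beta``."""
        eta, w = self._weights(beta)
        S0_g, W_t, denom = self._denoms(w)
        ll = float(eta[self.event_pos].sum() - np.log(denom).sum())

        wX = w[:, None] * self.X
        S1_suffix = np.cumsum(wX[::-1], axis=0)[::-1]
        S1_g = S1_suffix[self.risk_start]
        ge = self.g_of_event
        if self.ties == "efron":
            S1_t = np.zeros((self.G, self.p))
            np.add.at(S1_t, ge, wX[self.event_pos])
            Num = S1_g[ge] - self.frac[:, None] * S1_t[ge]
        else:
            Num = S1_g[ge]
        Xbar = Num / denom[:, None]
        score = self.X[self.event_pos].sum(axis=0) - Xbar.sum(axis=0)

        invd = 1.0 / denom
        A_g = np.bincount(ge, weights=invd, minlength=self.G)
        cumA = np.concatenate([[0.0], np.cumsum(A_g)])
        a = cumA[self.g_upto]
        if self.ties == "efron":
            B_g = np.bincount(ge, weights=self.frac * invd, minlength=self.G)
            a = a.copy()
            a[self.event_pos] -= B_g[ge]
        wa = w * a
        info = self.X.T @ (self.X * wa[:, None]) - Xbar.T @ Xbar
        return ll, score, info

    def event_design_and_means(self, beta: np.ndarray):
        """Per-event covariate rows, risk-set means and event times
        (Schoenfeld residual ingredients)."""
        _, w = self._weights(beta)
        S0_g, W_t, denom = self._denoms(w)
        wX = w[:, None] * self.X
        S1_suffix = np.cumsum(wX[::-1], axis=0)[::-1]
        S1_g = S1_suffix[self.risk_start]
        ge = self.g_of_event
        if self.ties == "efron":
            S1_t = np.zeros((self.G, self.p))
            np.add.at(S1_t, ge, wX[self.event_pos])
            Num = S1_g[ge] - self.frac[:, None] * S1_t[ge]
        else:
            Num = S1_g[ge]
        Xbar = Num / denom[:, None]
        return self.X[self.event_pos], Xbar, self.t[self.event_pos]

    def baseline_increments(self, beta: np.ndarray):
        """Breslow increments ``d_g / S0(t_g)`` at distinct event times."""
        _, w = self._weights(beta)
        S0_g, _, _ = self._denoms(w)
        return self.ut, self.d_g / S0_g


class GroupedPartialLikelihood:
    """Partial likelihood for a design ``[X | group indicators]``.

    Numerically identical to :class:`PartialLikelihood` on the expanded
    design, but the indicator block is never materialized: because each row
    belongs to exactly one group, risk-set sums over groups reduce to
    bincount scatters at event-time resolution followed by reversed
    cumulative sums, and the diagonal part of the information is a single
    weighted bincount.  This is what makes random-intercept fits with
    hundreds of regions and tens of thousands of patients cheap.
    """

    def __init__(self, times, events, X, groups, n_groups, ties: str = "efron",
                 offset=None):
        if ties not in {"efron", "breslow"}:
            raise ValueError("ties must be 'efron' or 'breslow'")
        times = np.asarray(times, dtype=float)
        d = np.asarray(events, dtype=float)
        X = np.ascontiguousarray(X, dtype=float)
        groups = np.asarray(groups, dtype=np.intp)
        n = times.shape[0]
        order = np.argsort(times, kind="stable")
        self.ties = ties
        self.n = n
        self.pc = X.shape[1]
        self.q = int(n_groups)
        self.p = self.pc + self.q
        self.X = X[order]
        self.gidx = groups[order]
        self.t = times[order]
        self.d = d[order].astype(bool)
        self.offset = (
            np.zeros(n) if offset is None else np.asarray(offset, dtype=float)[order]
        )
        self.event_pos = np.flatnonzero(self.d)
        if self.event_pos.size == 0:
            raise ValueError("dataset contains no events")
        ev_times = self.t[self.event_pos]
        self.ut = np.unique(ev_times)
        self.G = self.ut.size
        self.risk_start = np.searchsorted(self.t, self.ut, side="left")
        self.g_of_event = np.searchsorted(self.ut, ev_times)
        self.d_g = np.bincount(self.g_of_event, minlength=self.G).astype(float)
        first = np.concatenate([[0], np.cumsum(self.d_g)[:-1]]).astype(int)
        self.l_within = np.arange(self.event_pos.size) - first[self.g_of_event]
        self.tie_free = bool(np.all(self.d_g == 1))
        if ties == "efron" and not self.tie_free:
            self.frac = self.l_within / self.d_g[self.g_of_event]
        else:
            self.frac = None  # Efron == Breslow without ties
        self.g_upto = np.searchsorted(self.ut, self.t, side="right")
        # scatter target rows: subject i leaves the risk pool after event
        # time index g_upto[i] - 1; subjects with g_upto == 0 never enter
        self.at_risk = self.g_upto >= 1
        self.scatter_time = self.g_upto[self.at_risk] - 1
        self.scatter_flat = self.scatter_time * self.q + self.gidx[self.at_risk]
        self.ev_flat = self.g_of_event * self.q + self.gidx[self.event_pos]
        self.ev_count_by_group = np.bincount(
            self.gidx[self.event_pos], minlength=self.q
        ).astype(float)
        self.ev_sum_X = self.X[self.event_pos].sum(axis=0)

    def _weights(self, theta: np.ndarray):
        beta, r = theta[: self.pc], theta[self.pc:]
        eta = self.X @ beta + r[self.gidx] + self.offset
        eta = np.clip(eta, -500, 500)
        return eta, np.exp(eta)

    def _denoms(self, w: np.ndarray):
        S0_suffix = np.cumsum(w[::-1])[::-1]
        S0_g = S0_suffix[self.risk_start]
        if self.frac is not None:
            W_t = np.bincount(self.g_of_event, weights=w[self.event_pos],
                              minlength=self.G)
            denom = S0_g[self.g_of_event] - self.frac * W_t[self.g_of_event]
        else:
            denom = S0_g[self.g_of_event]
        return S0_g, denom

    def loglik(self, theta: np.ndarray) -> float:
        eta, w = self._weights(theta)
        _, denom = self._denoms(w)
        return float(eta[self.event_pos].sum() - np.log(denom).sum())

    def loglik_score_info(self, theta: np.ndarray):
        eta, w = self._weights(theta)
        S0_g, denom = self._denoms(w)
        ll = float(eta[self.event_pos].sum() - np.log(denom).sum())
        ge = self.g_of_event
        ev = self.event_pos
        wr = w[self.at_risk]

        # group-block risk sums R[k, g] = sum of w over group-g members at
        # risk at event time k  (scatter + reversed cumulative sum)
        R = np.bincount(self.scatter_flat, weights=wr, minlength=self.G * self.q)
        R = R.reshape(self.G, self.q)
        np.cumsum(R[::-1], axis=0, out=R[::-1])
        # dense-block risk sums S1c[k, :]
        wX = w[:, None] * self.X
        S1c = np.empty((self.G, self.pc))
        for j in range(self.pc):
            col = np.bincount(self.scatter_time, weights=wX[self.at_risk, j],
                              minlength=self.G)
            S1c[:, j] = np.cumsum(col[::-1])[::-1]

        if self.frac is not None:
            T = np.bincount(self.ev_flat, weights=w[ev],
                            minlength=self.G * self.q).reshape(self.G, self.q)
            S1c_t = np.empty((self.G, self.pc))
            for j in range(self.pc):
                S1c_t[:, j] = np.bincount(ge, weights=wX[ev, j], minlength=self.G)
            Num = np.concatenate(
                [S1c[ge] - self.frac[:, None] * S1c_t[ge],
                 R[ge] - self.frac[:, None] * T[ge]],
                axis=1,
            )
        else:
            Num = np.concatenate([S1c[ge], R[ge]], axis=1)
        Xbar = Num
        Xbar /= denom[:, None]

        colsum = Xbar.sum(axis=0)
        score = np.concatenate(
            [self.ev_sum_X - colsum[: self.pc],
             self.ev_count_by_group - colsum[self.pc:]]
        )

        invd = 1.0 / denom
        A_g = np.bincount(ge, weights=invd, minlength=self.G)
        cumA = np.concatenate([[0.0], np.cumsum(A_g)])
        a = cumA[self.g_upto]
        if self.frac is not None:
            B_g = np.bincount(ge, weights=self.frac * invd, minlength=self.G)
            a[ev] -= B_g[ge]
        wa = w * a

        info = np.empty((self.p, self.p))
        info[: self.pc, : self.pc] = self.X.T @ (self.X * wa[:, None])
        t1z = np.empty((self.q, self.pc))
        waX = wa[:, None] * self.X
        for j in range(self.pc):
            t1z[:, j] = np.bincount(self.gidx, weights=waX[:, j], minlength=self.q)
        info[: self.pc, self.pc:] = t1z.T
        info[self.pc:, : self.pc] = t1z
        zz = np.diag(np.bincount(self.gidx, weights=wa, minlength=self.q))
        info[self.pc:, self.pc:] = zz
        info -= Xbar.T @ Xbar
        return ll, score, info


def newton_penalized(
    engine: PartialLikelihood,
    penalty: np.ndarray | None = None,
    theta0: np.ndarray | None = None,
    max_iter: int = 60,
    tol_score: float = 1e-8,
    tol_rel: float = 1e-10,
):
    """Maximize ``loglik(theta) - 0.5 * theta' diag(penalty) theta``.

    Newton--Raphson with Cholesky solves (ridge jitter on failure) and
    step-halving whenever a proposed step decreases the penalized
    objective.  Returns ``(theta, info_at_opt, diagnostics_dict)``.
    """
    p = engine.p
    pen = np.zeros(p) if penalty is None else np.asarray(penalty, dtype=float)
    theta = np.zeros(p) if theta0 is None else np.asarray(theta0, dtype=float).copy()
    ll, g, H = engine.loglik_score_info(theta)
    pll = ll - 0.5 * float(theta @ (pen * theta))
    converged = False
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        gp = g - pen * theta
        if np.max(np.abs(gp)) < tol_score:
            converged = True
            break
        Hp = H + np.diag(pen)
        delta = _solve_spd(Hp, gp)
        step = 1.0
        for _ in range(35):
            cand = theta + step * delta
            ll_c = engine.loglik(cand)
            pll_c = ll_c - 0.5 * float(cand @ (pen * cand))
            if pll_c >= pll - 1e-12 * (abs(pll) + 1):
                break
            step *= 0.5
        else:  # no acceptable step; stop here
            break
        theta = cand
        prev = pll
        ll, g, H = engine.loglik_score_info(theta)
        pll = ll - 0.5 * float(theta @ (pen * theta))
        if abs(pll - prev) <= tol_rel * (abs(prev) + 1):
            converged = True
            break
    free = pen == 0
    if np.any(np.abs(theta[free]) > 20):
        warnings.warn(
            "coefficient magnitude exceeds 20; the partial likelihood may be "
            "monotone (perfect separation of risk sets)",
            MonotoneLikelihoodWarning,
            stacklevel=2,
        )
    diag = {"converged": bool(converged), "n_iter": n_iter, "loglik": ll,
            "penalized_loglik": pll, "max_score": float(np.max(np.abs(g - pen * theta)))}
    return theta, H, diag


def _solve_spd(H: np.ndarray, g: np.ndarray) -> np.ndarray:
    jitter = 0.0
    for _ in range(8):
        try:
            c, low = linalg.cho_factor(
                H + jitter * np.eye(H.shape[0]), check_finite=False
            )
            return linalg.cho_solve((c, low), g, check_finite=False)
        except linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-8 * np.trace(H) / H.shape[0], 1e-12)
    return np.linalg.lstsq(H, g, rcond=None)[0]


# ---------------------------------------------------------------------------
# public fitting API


@dataclass
class CoxFit:
    """Fitted Cox proportional-hazards model."""

    params: pd.Series
    se: pd.Series
    cov: pd.DataFrame
    loglik: float
    loglik_null: float
    n_params: int
    ties: str
    converged: bool
    n_iter: int
    n: int
    n_events: int
    baseline_hazard: pd.DataFrame
    _engine: PartialLikelihood = field(repr=False, default=None)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        return hazard_ratios(self, level=level)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[1] == 0:
        raise ValueError("empty design matrix")
    Xc = X - X.mean(axis=0)  # the partial likelihood cannot identify constants
    _, R, piv = linalg.qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [names[piv[j]] for j in range(len(diag)) if diag[j] <= tol]
    if bad or (diag.size and diag.min() == 0):
        raise ValueError(
            f"design matrix is rank deficient; collinear or constant columns: {bad}"
        )


def fit_cox(
    dataset: Dataset,
    specs: Sequence[CovariateSpec],
    ties: str = "efron",
) -> CoxFit:
    """Fit the baseline Cox model by Newton--Raphson.

    Convergence: max |score| < 1e-8 or relative log-likelihood change
    < 1e-10, with step-halving on any decrease.
    """
    if dataset.n_events < 1:
        raise ValueError("cannot fit a Cox model with zero events")
    X, names = encode_design(dataset, specs)
    _check_rank(X, names)
    engine = PartialLikelihood(dataset.times(), dataset.events(), X, ties=ties)
    ll_null = engine.loglik(np.zeros(X.shape[1]))
    theta, H, diag = newton_penalized(engine)
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    ut, inc = engine.baseline_increments(theta)
    baseline = pd.DataFrame({"time": ut, "cumulative_hazard": np.cumsum(inc)})
    return CoxFit(
        params=pd.Series(theta, index=names),
        se=pd.Series(se, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglik=diag["loglik"],
        loglik_null=ll_null,
        n_params=len(names),
        ties=ties,
        converged=diag["converged"],
        n_iter=diag["n_iter"],
        n=dataset.n,
        n_events=dataset.n_events,
        baseline_hazard=baseline,
        _engine=engine,
    )


def hazard_ratios(fit: CoxFit, level: float = 0.95) -> pd.DataFrame:
    """Hazard ratios with Wald confidence intervals and two-sided p-values."""
    z = stats.norm.ppf(0.5 + level / 2)
    beta = fit.params.to_numpy()
    se = fit.se.to_numpy()
    zstat = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    return pd.DataFrame(
        {
            "HR": np.exp(beta),
            "CI_low": np.exp(beta - z * se),
            "CI_high": np.exp(beta + z * se),
            "p": 2 * stats.norm.sf(np.abs(zstat)),
        },
        index=fit.params.index,
    )


def schoenfeld_ph_test(fit: CoxFit, dataset: Dataset | None = None) -> dict:
    """Proportional-hazards check from scaled Schoenfeld residuals.

    Score test of zero slope of the scaled residuals against event time
    (Grambsch--Therneau): per-covariate chi-square statistics on 1 df and a
    global test on p df.
    """
    engine = fit._engine
    if engine is None:
        raise ValueError("fit does not carry its engine; refit before testing")
    if fit.n_events < 2:
        raise ValueError("need at least 2 events for the PH test")
    beta = fit.params.to_numpy()
    Xe, Xbar, g = engine.event_design_and_means(beta)
    resid = Xe - Xbar
    d = resid.shape[0]
    gc = g - g.mean()
    ssg = float(gc @ gc)
    if ssg == 0:
        raise ValueError("all events share one time; PH slope test undefined")
    _, _, info = engine.loglik_score_info(beta)
    info_inv = np.linalg.inv(info)
    u = resid.T @ gc
    v = info_inv @ u
    per_chi2 = d * v**2 / (np.diag(info_inv) * ssg)
    per_p = stats.chi2.sf(per_chi2, 1)
    global_chi2 = float(d * (u @ v) / ssg)
    names = list(fit.params.index)
    table = pd.DataFrame({"chi2": per_chi2, "p": per_p}, index=names)
    return {
        "table": table,
        "global_chi2": global_chi2,
        "global_df": len(names),
        "global_p": float(stats.chi2.sf(global_chi2, len(names))),
    }


def vif(X: np.ndarray, names: Sequence[str] | None = None) -> pd.Series:
    """Variance inflation factor ``1 / (1 - R^2_j)`` per design column.

    Perfectly collinear columns yield ``inf`` and are named in a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("VIF needs at least two design columns")
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    out = np.empty(X.shape[1])
    offenders = []
    ones = np.ones((X.shape[0], 1))
    for j in range(X.shape[1]):
        yj = X[:, j]
        if np.ptp(yj) == 0:
            raise ValueError(f"constant column {names[j]!r} has undefined VIF")
        others = np.concatenate([ones, np.delete(X, j, axis=1)], axis=1)
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        tss = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / tss
        if r2 >= 1.0 - 1e-12:
            out[j] = np.inf
            offenders.append(names[j])
        else:
            out[j] = 1.0 / (1.0 - r2)
    if offenders:
        warnings.warn(
            f"perfect collinearity: infinite VIF for columns {offenders}",
            stacklevel=2,
        )
    return pd.Series(out, index=names)


def breslow_baseline(fit: CoxFit, dataset: Dataset | None = None) -> pd.DataFrame:
    """Breslow cumulative baseline hazard: increments ``d_i / sum_{R(t_i)}
    exp(x beta)`` at each distinct event time."""
    return fit.baseline_hazard.copy()
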