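"""Moran eigenvector spatial filtering (MESF).

Given a binary contiguity matrix ``C`` over ``n`` regions, the doubly
centered matrix ``M C M`` with ``M = I - 11'/n`` has mutually orthogonal
eigenvectors, each a distinct map pattern whose Moran coefficient is
proportional to its eigenvalue: ``MC_i = (n / S0) * lambda_i``.  A stepwise
regression of a per-region target (here: estimated random effects of a
multilevel survival model) on high-autocorrelation eigenvectors splits the
target into a spatially structured fit and a spatially unstructured
residual.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .spatial_weights import AdjacencyGraph

__all__ = [
    "EigenBasis",
    "MESFSelection",
    "doubly_center",
    "eigendecompose",
    "candidate_set",
    "select_eigenvectors",
    "write_basis_csv",
    "read_basis_csv",
]

_NULL_TOL = 1e-10


def doubly_center(graph: AdjacencyGraph) -> np.ndarray:
    """Return ``M C M`` where ``M = I - 11'/n`` (projector onto mean-zero
    vectors).  Every row and column of the result sums to zero."""
    n = graph.n
    if n < 2:
        raise ValueError("need at least 2 regions to doubly center")
    C = graph.matrix()
    row = C.mean(axis=1, keepdims=True)
    col = C.mean(axis=0, keepdims=True)
    grand = C.mean()
    return C - row - col + grand


@dataclass(frozen=True)
class EigenBasis:
    """Spectral basis of the doubly centered weights matrix.

    ``vectors`` holds ``m = n - 1`` orthonormal columns sorted by descending
    eigenvalue; the trivial constant eigenvector (eigenvalue 0) is removed so
    that every retained column is exactly orthogonal to the constant.  ``mc``
    holds each column's Moran coefficient ``(n / S0) * eigenvalue``.
    """

    vectors: np.ndarray
    eigenvalues: np.ndarray
    mc: np.ndarray
    graph: AdjacencyGraph = field(repr=False)

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def m(self) -> int:
        return self.vectors.shape[1]


def _fix_signs(E: np.ndarray) -> np.ndarray:
    """First coordinate of non-negligible magnitude made positive, per column."""
    E = E.copy()
    for j in range(E.shape[1]):
        col = E[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-9)
        if nz.size and col[nz[0]] < 0:
            E[:, j] = -col
    return E


def eigendecompose(mcm: np.ndarray, graph: AdjacencyGraph) -> EigenBasis:
    """Eigendecomposition of a doubly centered weights matrix.

    The numerical null space always contains the constant vector; that
    subspace is rotated so the constant direction is isolated, and the
    constant column is dropped (it carries no spatial pattern and would
    otherwise break orthogonality to the intercept).
    """
    mcm = np.asarray(mcm, dtype=float)
    n = graph.n
    if mcm.shape != (n, n):
        raise ValueError("matrix shape does not match graph size")
    if not np.allclose(mcm, mcm.T, atol=1e-10):
        raise ValueError("matrix is not symmetric within tolerance")
    lam, E = np.linalg.eigh(mcm)
    # rotate the null space so one column is exactly the constant direction
    scale = max(1.0, np.max(np.abs(lam)))
    null = np.flatnonzero(np.abs(lam) <= _NULL_TOL * scale * n)
    const = np.full(n, 1.0 / np.sqrt(n))
    if null.size:
        B = E[:, null]
        # complement of the constant inside the null space, re-orthonormalized
        P = B - np.outer(const, const @ B)
        Q, R = np.linalg.qr(P)
        keep = np.flatnonzero(np.abs(np.diag(R)) > 1e-8)
        B_new = np.concatenate([Q[:, keep], const[:, None]], axis=1)
        E = np.concatenate([np.delete(E, null, axis=1), B_new], axis=1)
        lam = np.concatenate([np.delete(lam, null), np.zeros(B_new.shape[1])])
    # drop the column closest to the constant direction
    align = np.abs(const @ E)
    drop = int(np.argmax(align))
    E = np.delete(E, drop, axis=1)
    lam = np.delete(lam, drop)
    order = np.argsort(-lam, kind="stable")
    E, lam = E[:, order], lam[order]
    E = _fix_signs(E)
    s0 = graph.s0
    mc = (n / s0) * lam if s0 > 0 else np.zeros_like(lam)
    return EigenBasis(vectors=E, eigenvalues=lam, mc=mc, graph=graph)


def candidate_set(basis: EigenBasis, mc_ratio_threshold: float = 0.25) -> list[int]:
    """Indices of eigenvectors with ``mc_i / mc_max >= threshold``.

    Only positive Moran coefficients qualify (the filtering concerns positive
    spatial autocorrelation); an empty list is returned when no eigenvalue is
    positive.
    """
    if not (0 < mc_ratio_threshold <= 1):
        raise ValueError("mc_ratio_threshold must lie in (0, 1]")
    if basis.m == 0:
        return []
    mc_max = basis.mc.max(initial=0.0)
    if mc_max <= 0:
        return []
    return [int(i) for i in np.flatnonzero(basis.mc >= mc_ratio_threshold * mc_max)]


@dataclass(frozen=True)
class MESFSelection:
    """Result of stepwise eigenvector selection against a per-region target.

    ``ssre`` is the fitted spatially structured component ``E_k @ beta``
    (mean-zero); ``residual = target - ssre`` carries the target mean, so
    ``ssre + residual`` reproduces the target exactly.
    """

    selected_indices: tuple[int, ...]
    coefficients: np.ndarray
    ssre: np.ndarray
    residual: np.ndarray
    r_squared: float
    target_mean: float
    selection_trace: tuple[dict, ...]


def _step_pvalues(b: np.ndarray, rss_each: np.ndarray, df: int) -> np.ndarray:
    """Two-sided t p-values for orthonormal-regressor coefficients ``b`` with
    the residual sum of squares each model would have and ``df`` residual
    degrees of freedom.  A zero variance estimate gives p = 0 for a nonzero
    coefficient (perfect fit) and p = 1 for a zero one."""
    b = np.atleast_1d(np.asarray(b, dtype=float))
    rss_each = np.atleast_1d(np.asarray(rss_each, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = rss_each / df
        t = np.where(
            sigma2 > 0,
            np.abs(b) / np.sqrt(np.where(sigma2 > 0, sigma2, 1.0)),
            np.where(np.abs(b) > 0, np.inf, 0.0),
        )
    return 2.0 * stats.t.sf(t, df)


def select_eigenvectors(
    target: np.ndarray,
    basis: EigenBasis,
    candidates: list[int],
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> MESFSelection:
    """Forward-stepwise least squares of ``target`` on candidate eigenvectors.

    The target is centered first (the basis columns are mean-zero).  Because
    candidates are mutually orthonormal each coefficient equals ``e_j'y``
    regardless of which other columns are included; ties in p-value are
    broken by larger absolute correlation, then lower index, making the
    procedure deterministic.  At each step the best candidate enters if its
    p-value is at most ``alpha_enter``; any included vector whose p-value
    rises above ``alpha_remove`` is then removed.

    The residual variance for the t-tests is estimated from the model
    containing *all* candidates whenever enough degrees of freedom remain
    (at least 5).  With orthonormal regressors this keeps the per-candidate
    false-entry rate at ``alpha_enter`` under a white-noise target; the
    naive step-wise variance estimate shrinks as large coefficients are
    absorbed and systematically over-selects.  When the candidate set is
    nearly a full basis the per-step estimate is used instead.
    """
    y = np.asarray(target, dtype=float)
    if y.shape != (basis.n,):
        raise ValueError("target length must equal the number of regions")
    if not np.all(np.isfinite(y)):
        raise ValueError("target contains non-finite entries")
    mean = float(y.mean())
    yc = y - mean
    tss = float(yc @ yc)
    n = basis.n
    cand = list(dict.fromkeys(int(c) for c in candidates))
    b_all = {j: float(basis.vectors[:, j] @ yc) for j in cand}

    included: list[int] = []
    trace: list[dict] = []
    df_full = n - 1 - len(cand)
    fixed_variance = df_full >= 5
    if fixed_variance:
        rss_full = max(tss - sum(b ** 2 for b in b_all.values()), 0.0)
    if cand and tss > 0:
        max_steps = 4 * len(cand) + 4
        for _ in range(max_steps):
            changed = False
            inc_ss = sum(b_all[j] ** 2 for j in included)
            # --- forward: candidate with smallest p-value
            outside = [j for j in cand if j not in included]
            if outside:
                k = len(included)
                df = df_full if fixed_variance else n - 1 - (k + 1)
                if df > 0:
                    bs = np.array([b_all[j] for j in outside])
                    if fixed_variance:
                        rss_each = np.full(len(outside), rss_full)
                    else:
                        rss_each = np.maximum(tss - inc_ss - bs**2, 0.0)
                    ps = _step_pvalues(bs, rss_each, df)
                    # order: p ascending, |b| descending, index ascending
                    best = min(
                        range(len(outside)),
                        key=lambda i: (ps[i], -abs(bs[i]), outside[i]),
                    )
                    if ps[best] <= alpha_enter:
                        j = outside[best]
                        included.append(j)
                        trace.append(
                            {"action": "enter", "index": j, "p_value": float(ps[best]),
                             "coefficient": b_all[j]}
                        )
                        changed = True
            # --- backward: drop anything no longer significant
            while included:
                k = len(included)
                df = df_full if fixed_variance else n - 1 - k
                if df <= 0:
                    break
                inc_ss = sum(b_all[j] ** 2 for j in included)
                rss = rss_full if fixed_variance else max(tss - inc_ss, 0.0)
                bs = np.array([b_all[j] for j in included])
                # p-value of each included coefficient in the current model
                ps = _step_pvalues(bs, np.full(len(included), rss), df)
                worst = max(range(len(included)), key=lambda i: (ps[i], -abs(bs[i]), included[i]))
                if ps[worst] > alpha_remove:
                    j = included.pop(worst)
                    trace.append(
                        {"action": "remove", "index": j, "p_value": float(ps[worst]),
                         "coefficient": b_all[j]}
                    )
                    changed = True
                else:
                    break
            if not changed:
                break

    included_arr = np.array(included, dtype=int)
    coefs = np.array([b_all[j] for j in included], dtype=float)
    if included:
        ssre = basis.vectors[:, included_arr] @ coefs
    else:
        ssre = np.zeros(n)
    residual = y - ssre
    r2 = float((coefs @ coefs) / tss) if tss > 0 else 0.0
    return MESFSelection(
        selected_indices=tuple(included),
        coefficients=coefs,
        ssre=ssre,
        residual=residual,
        r_squared=r2,
        target_mean=mean,
        selection_trace=tuple(trace),
    )


# ---------------------------------------------------------------------------
# serialization


def write_basis_csv(basis: EigenBasis, csv_path, meta_path) -> None:
    """Basis as CSV (region label + one column per eigenvector) plus JSON
    metadata (eigenvalues, Moran coefficients, graph fingerprint)."""
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["region_id"] + [f"ev{j + 1}" for j in range(basis.m)])
        for i, r in enumerate(basis.graph.region_ids):
            w.writerow([r] + [repr(float(v)) for v in basis.vectors[i]])
    meta = {
        "eigenvalues": basis.eigenvalues.tolist(),
        "mc": basis.mc.tolist(),
        "n": basis.n,
        "s0": basis.graph.s0,
        "graph_hash": _graph_hash(basis.graph),
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_basis_csv(csv_path, meta_path, graph: AdjacencyGraph) -> EigenBasis:
    with open(meta_path) as fh:
        meta = json.load(fh)
    if meta["graph_hash"] != _graph_hash(graph):
        raise ValueError("basis metadata does not match the supplied graph")
    rows = []
    labels = []
    with open(csv_path, newline="") as fh:
        rdr = csv.reader(fh)
        next(rdr)
        for row in rdr:
            labels.append(row[0])
            rows.append([float(v) for v in row[1:]])
    if labels != list(graph.region_ids):
        raise ValueError("region order in basis CSV does not match the graph")
    return EigenBasis(
        vectors=np.asarray(rows),
        eigenvalues=np.asarray(meta["eigenvalues"], dtype=float),
        mc=np.asarray(meta["mc"], dtype=float),
        graph=graph,
    )


def _graph_hash(graph: AdjacencyGraph) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update("|".join(graph.region_ids).encode())
    for a, b in sorted(graph.edges):
        h.update(f"{a}~{b}".encode())
    return h.hexdigest()[:16]
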