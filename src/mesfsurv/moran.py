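"""Moran's I spatial autocorrelation statistic.

Implements the global statistic with binary (non-row-standardized) weights,

    I = (n / S0) * sum_ij c_ij z_i z_j / sum_i z_i^2,   z = x - mean(x),

with analytic moments under the randomization assumption (normality
available as an option) and a conditional permutation test.  Binary weights
keep the statistic consistent with the Moran-eigenvector construction, where
an eigenvector of MCM has Moran's I equal to ``(n / S0) * eigenvalue``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spatial_weights import AdjacencyGraph

__all__ = ["MoranResult", "morans_i", "morans_i_permutation"]


@dataclass(frozen=True)
class MoranResult:
    i_value: float
    expectation: float
    variance: float
    z_score: float
    p_value: float
    assumption: str = "randomization"
    alternative: str = "greater"
    n_permutations: int = 0
    permutation_p: float | None = None
    seed: int | None = None

    def display_p(self, which: str = "analytic") -> str:
        """p-value formatted to 4 decimals; '0.0000' means < 0.00005."""
        p = self.p_value if which == "analytic" else self.permutation_p
        return f"{p:.4f}"


def _checked_z(values: np.ndarray, graph: AdjacencyGraph) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.shape != (graph.n,):
        raise ValueError("values length must equal the number of regions")
    if not np.all(np.isfinite(x)):
        raise ValueError("values contain non-finite entries")
    if graph.s0 == 0:
        raise ValueError("Moran's I undefined on an edgeless graph (S0 = 0)")
    z = x - x.mean()
    if not np.any(z != 0):
        raise ValueError("Moran's I undefined for constant values")
    return z


def _i_stat(z: np.ndarray, graph: AdjacencyGraph) -> float:
    i, j = graph.edge_indices()
    num = 2.0 * float(z[i] @ z[j])  # both orientations of each edge
    return (graph.n / graph.s0) * num / float(z @ z)


def morans_i(
    values: np.ndarray,
    graph: AdjacencyGraph,
    assumption: str = "randomization",
    alternative: str = "greater",
) -> MoranResult:
    """Moran's I with analytic inference.

    ``assumption`` is ``'randomization'`` (default) or ``'normality'``;
    ``alternative`` is ``'greater'`` (one-sided upper tail, default),
    ``'less'`` or ``'two-sided'``.
    """
    if graph.n < 3:
        raise ValueError("analytic Moran inference needs at least 3 regions")
    z = _checked_z(values, graph)
    n = graph.n
    s0 = float(graph.s0)
    I = _i_stat(z, graph)
    ei = -1.0 / (n - 1)
    # binary symmetric weights: S1 = 2*S0, S2 = 4 * sum(deg^2)
    s1 = 2.0 * s0
    deg = graph.degrees()
    s2 = float(4.0 * (deg @ deg))
    if assumption == "randomization":
        z2 = float(z @ z)
        b2 = n * float((z**2) @ (z**2)) / z2**2
        num = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0) - b2 * (
            (n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0
        )
        var = num / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - ei * ei
    elif assumption == "normality":
        var = (n * n * s1 - n * s2 + 3 * s0 * s0) / ((n * n - 1) * s0 * s0) - ei * ei
    else:
        raise ValueError("assumption must be 'randomization' or 'normality'")
    zscore = (I - ei) / np.sqrt(var)
    if alternative == "greater":
        p = float(stats.norm.sf(zscore))
    elif alternative == "less":
        p = float(stats.norm.cdf(zscore))
    elif alternative == "two-sided":
        p = float(2.0 * stats.norm.sf(abs(zscore)))
    else:
        raise ValueError("alternative must be 'greater', 'less' or 'two-sided'")
    return MoranResult(
        i_value=float(I),
        expectation=ei,
        variance=float(var),
        z_score=float(zscore),
        p_value=p,
        assumption=assumption,
        alternative=alternative,
    )


def morans_i_permutation(
    values: np.ndarray,
    graph: AdjacencyGraph,
    n_perm: int = 999,
    seed: int | None = None,
    assumption: str = "randomization",
    alternative: str = "greater",
) -> MoranResult:
    """Moran's I with a permutation (conditional randomization) pseudo p-value.

    ``pseudo_p = (1 + #{I_perm >= I_obs}) / (n_perm + 1)`` for the upper
    tail; lower tail and two-sided analogues are available.  Reproducible
    given ``seed``.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    base = morans_i(values, graph, assumption=assumption, alternative=alternative)
    z = _checked_z(values, graph)
    rng = np.random.default_rng(seed)
    i_idx, j_idx = graph.edge_indices()
    denom = float(z @ z)
    scale = graph.n / graph.s0 / denom
    sims = np.empty(n_perm)
    for k in range(n_perm):
        zp = rng.permutation(z)
        sims[k] = scale * 2.0 * float(zp[i_idx] @ zp[j_idx])
    if alternative == "greater":
        extreme = int(np.sum(sims >= base.i_value))
    elif alternative == "less":
        extreme = int(np.sum(sims <= base.i_value))
    else:
        extreme = int(np.sum(np.abs(sims - sims.mean()) >= abs(base.i_value - sims.mean())))
    pseudo_p = (1.0 + extreme) / (n_perm + 1.0)
    return MoranResult(
        i_value=base.i_value,
        expectation=base.expectation,
        variance=base.variance,
        z_score=base.z_score,
        p_value=base.p_value,
        assumption=assumption,
        alternative=alternative,
        n_permutations=n_perm,
        permutation_p=float(pseudo_p),
        seed=seed,
    )
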