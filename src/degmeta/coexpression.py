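"""Co-expression connectivity scores over the gene universe (WGCNA-lite).

The overlap null weights its sampling by how co-expressed each universe
gene is, so that the simulated DEG lists inherit the dependence structure
of real transcriptomes.  The chain is the standard weighted co-expression
construction: Pearson correlation -> soft-threshold power beta (chosen by
scale-free topology fit) -> adjacency a_ij -> topological overlap matrix
(TOM) -> per-gene connectivity k_i = sum_j TOM_ij.

Only connectivity is needed downstream; module detection, eigengenes and
dendrogram cutting are deliberately out of scope.

Expression matrices are plain ``pandas.DataFrame`` objects with genes as
the index and samples as columns; adjacency/TOM are ``numpy`` arrays (or
DataFrames when the input carries labels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityModel",
    "SoftThresholdScan",
    "adjacency",
    "build_connectivity_model",
    "connectivity_scores",
    "connectivity_weights",
    "correlation_matrix",
    "pick_soft_threshold",
    "tom_similarity",
]


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between gene expression rows.

    Requires at least 3 samples; a zero-variance gene row is an error
    (it has no defined correlation and should be removed upstream).
    """
    if expr.shape[1] < 3:
        raise ValueError(f"need >= 3 samples, got {expr.shape[1]}")
    values = np.asarray(expr, dtype=float)
    sd = values.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [str(expr.index[i]) for i in dead[:5]]
        raise ValueError(f"zero-variance gene rows: {', '.join(names)}")
    corr = np.corrcoef(values)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=expr.index, columns=expr.index)


def adjacency(corr, beta: float, network_type: str = "unsigned"):
    """Soft-threshold a correlation matrix into an adjacency in [0, 1].

    unsigned: a_ij = |cor_ij|^beta; signed: a_ij = ((1 + cor_ij) / 2)^beta.
    The diagonal is set to 1 by convention.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    c = np.asarray(corr, dtype=float)
    if network_type == "unsigned":
        a = np.abs(c) ** beta
    elif network_type == "signed":
        a = ((1.0 + c) / 2.0) ** beta
    else:
        raise ValueError(f"network_type must be 'unsigned' or 'signed', got {network_type!r}")
    np.fill_diagonal(a, 1.0)
    if isinstance(corr, pd.DataFrame):
        return pd.DataFrame(a, index=corr.index, columns=corr.columns)
    return a


def tom_similarity(adj, block_size: int | None = None):
    """Topological overlap similarity of a weighted adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu;
    TOM_ii = 1.  High overlap means two genes share the same weighted
    neighbourhood even if their direct edge is moderate.

    ``block_size`` computes the shared-neighbour term in row blocks to
    bound memory on large universes; results are identical to the
    single-block computation.
    """
    a = np.array(adj, dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, rtol=0.0, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a = (a + a.T) / 2.0  # remove float round-off asymmetry exactly
    if a.min() < 0 or a[~np.eye(a.shape[0], dtype=bool)].max(initial=0.0) > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    n = a.shape[0]
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    # np.einsum without optimization reduces each output element in a fixed
    # order, so blocked and single-pass results are bit-identical (a BLAS
    # matmul is not: its accumulation order depends on the block shape).
    if block_size is None or block_size >= n:
        shared = np.einsum("ij,jk->ik", a, a, optimize=False)
    else:
        shared = np.empty((n, n), dtype=float)
        for start in range(0, n, block_size):
            stop = min(start + block_size, n)
            shared[start:stop] = np.einsum("ij,jk->ik", a[start:stop], a, optimize=False)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return tom


def connectivity_scores(tom) -> pd.Series | np.ndarray:
    """Per-gene connectivity k_i = sum_{j != i} TOM_ij (row sum minus diagonal)."""
    t = np.asarray(tom, dtype=float)
    k = t.sum(axis=1) - np.diag(t)
    k = np.maximum(k, 0.0)  # guard tiny negative round-off on isolated genes
    if isinstance(tom, pd.DataFrame):
        return pd.Series(k, index=tom.index, name="connectivity")
    return k


@dataclass
class SoftThresholdScan:
    """Scale-free topology scan over candidate soft-threshold powers.

    ``fit_r2`` is the signed model fit: R^2 of the log10 p(k) ~ log10 k
    regression, negated when the slope is positive (scale-free networks
    have a negative slope).  The chosen power is the smallest one reaching
    ``r2_target``; if none does, the best-fitting power is used and a
    warning is logged.
    """

    candidate_powers: tuple[float, ...] = tuple(range(1, 21))
    r2_target: float = 0.8
    n_bins: int = 10
    fit_r2: dict[float, float] = field(default_factory=dict)
    mean_connectivity: dict[float, float] = field(default_factory=dict)
    chosen_power: float | None = None
    target_reached: bool = False


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    """Signed R^2 of the scale-free topology fit for a connectivity vector."""
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        return -1.0
    counts, edges = np.histogram(k, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    keep = counts > 0
    if keep.sum() < 2:
        return -1.0
    x = np.log10(centers[keep])
    y = np.log10(counts[keep] / counts.sum())
    if np.ptp(x) == 0:
        return -1.0
    fit = stats.linregress(x, y)
    r2 = fit.rvalue ** 2
    return -r2 if fit.slope > 0 else r2


def pick_soft_threshold(
    corr,
    scan: SoftThresholdScan | None = None,
    network_type: str = "unsigned",
) -> SoftThresholdScan:
    """Choose the soft-threshold power by scale-free topology fit.

    For each candidate power, adjacency and per-gene connectivity are
    computed, connectivity is binned, and log10 frequency is regressed on
    log10 connectivity.  Degenerate powers (all-zero connectivity, e.g.
    from an identity correlation matrix) score -1 and simply never reach
    the target, which routes such inputs through the warning path.
    """
    scan = scan or SoftThresholdScan()
    if not scan.candidate_powers:
        raise ValueError("candidate_powers must be nonempty")
    c = np.asarray(corr, dtype=float)
    for power in scan.candidate_powers:
        a = adjacency(c, power, network_type)
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        scan.mean_connectivity[power] = float(k.mean())
        scan.fit_r2[power] = float(_scale_free_fit(k, scan.n_bins))
    for power in scan.candidate_powers:
        if scan.fit_r2[power] >= scan.r2_target:
            scan.chosen_power = power
            scan.target_reached = True
            break
    else:
        scan.chosen_power = max(scan.candidate_powers, key=lambda p: scan.fit_r2[p])
        scan.target_reached = False
        logger.warning(
            "no candidate power reached scale-free fit R^2 >= %.2f; using best power %s (R^2 = %.3f)",
            scan.r2_target, scan.chosen_power, scan.fit_r2[scan.chosen_power],
        )
    return scan


@dataclass
class ConnectivityModel:
    """Adjacency/TOM matrices and per-gene connectivity over the universe."""

    power_beta: float
    network_type: str
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    connectivity: pd.Series

    @property
    def genes(self) -> list:
        return list(self.connectivity.index)


def build_connectivity_model(
    expr: pd.DataFrame,
    *,
    beta: float | None = None,
    network_type: str = "unsigned",
    scan: SoftThresholdScan | None = None,
    connectivity_basis: str = "tom",
    block_size: int | None = None,
) -> ConnectivityModel:
    """Run the full chain: correlation -> (beta scan) -> adjacency -> TOM -> k_i.

    ``connectivity_basis`` selects the TOM row sum (default, matching the
    use of TOM-based gene connectivity for null weighting) or the plain
    adjacency row sum as an alternative.
    """
    if connectivity_basis not in ("tom", "adjacency"):
        raise ValueError("connectivity_basis must be 'tom' or 'adjacency'")
    corr = correlation_matrix(expr)
    if beta is None:
        beta = pick_soft_threshold(corr, scan, network_type).chosen_power
    adj = adjacency(corr, beta, network_type)
    tom = tom_similarity(adj, block_size=block_size)
    basis = tom if connectivity_basis == "tom" else adj
    k = connectivity_scores(basis)
    return ConnectivityModel(
        power_beta=float(beta),
        network_type=network_type,
        adjacency=adj,
        tom=tom,
        connectivity=k,
    )


def connectivity_weights(universe_genes, connectivity: pd.Series) -> tuple[pd.Series, list]:
    """Sampling weights for an arbitrary universe, imputing missing genes.

    Genes present in DEG lists but absent from the expression universe get
    the median connectivity (excluding them would shrink the universe
    asymmetrically); the imputed genes are returned for flagging in output.
    """
    median = float(connectivity.median())
    weights = {}
    missing = []
    for g in universe_genes:
        if g in connectivity.index:
            weights[g] = float(connectivity[g])
        else:
            weights[g] = median
            missing.append(g)
    if missing:
        logger.info("%d universe genes absent from expression data; median connectivity imputed", len(missing))
    s = pd.Series(weights, name="weight")
    # Strictly positive weights are required by the sampler; nudge exact zeros.
    floor = max(s[s > 0].min() * 1e-6, 1e-12) if (s > 0).any() else 1e-12
    s[s <= 0] = floor
    return s, missing
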