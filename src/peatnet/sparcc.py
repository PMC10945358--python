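"""Compositionally robust correlation inference (SparCC) and network assembly.

Relative-abundance data are compositional: because each sample's fractions
sum to one, naive correlations between taxa are biased negative. SparCC
sidesteps the constraint by working with log-ratio variances

    t[i, j] = Var_samples( log(x_i / x_j) )
            = w_i + w_j - 2 * rho[i, j] * sqrt(w_i * w_j),

where w are the variances of the (unobserved) basis log-abundances. Under
approximate sparsity of the true correlations, summing t over j gives a
linear system for the basis variances:

    M w = t_rowsums,   M = diag(p - 1) + (ones - I),

after which ``rho[i, j] = (w_i + w_j - t[i, j]) / (2 sqrt(w_i w_j))``.
Strongly correlated pairs violate the sparsity assumption, so the strongest
pair above an exclusion threshold is iteratively removed from the sums and
the system re-solved.

Count uncertainty is handled by resampling: fractions are drawn from the
per-sample Dirichlet posterior (counts + 1 pseudocount), the basis
correlation estimated per draw, and the element-wise median returned.
Significance comes from a permutation null that shuffles each taxon's
counts across samples independently, destroying all between-taxon
association while preserving each taxon's marginal distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .otu import OtuTable

logger = logging.getLogger(__name__)

__all__ = [
    "SparccConfig",
    "CorrelationNetwork",
    "log_ratio_variances",
    "basis_correlations",
    "sparcc",
    "permutation_pvalues",
    "build_network",
]

_OMEGA_FLOOR = 1e-10


@dataclass(frozen=True)
class SparccConfig:
    """Estimation and filtering settings.

    The two downstream filters — ``correlation_threshold`` (default 0.6 on
    |rho|) and ``alpha`` (default 0.05) — are the study-level choices; the
    estimator internals (20 Dirichlet resamples, 0.1 exclusion threshold,
    10 exclusion rounds, 100 permutations, +1 pseudocount, median
    aggregation) follow the original method's conventions and are all
    configurable.
    """

    n_resamples: int = 20
    exclusion_threshold: float = 0.1
    max_exclusion_rounds: int = 10
    n_permutations: int = 100
    correlation_threshold: float = 0.6
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples < 1 or self.max_exclusion_rounds < 0:
            raise ValueError("counts must be >= 1 (rounds >= 0)")
        for name in ("exclusion_threshold", "correlation_threshold", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def log_ratio_variances(fractions) -> np.ndarray:
    """Pairwise variance of log-ratios, ``t[i,j] = Var(log(x_i/x_j))``.

    ``fractions`` is taxa x samples with strictly positive entries
    (pseudocounts or Dirichlet draws applied upstream). Computed from the
    covariance of log-fractions: Var(log x_i - log x_j) =
    C[i,i] + C[j,j] - 2 C[i,j], one matrix product instead of p^2 passes.
    """
    F = np.asarray(fractions, dtype=float)
    if F.ndim != 2:
        raise ValueError("fractions must be 2-D (taxa x samples)")
    p, n = F.shape
    if p < 4:
        raise ValueError(
            f"need >= 4 taxa for the basis-variance system, got {p}"
        )
    if n < 2:
        raise ValueError("need >= 2 samples")
    if (F <= 0).any():
        raise ValueError("fractions must be strictly positive")
    L = np.log(F)
    C = np.cov(L, ddof=1)
    v = np.diag(C)
    t = v[:, None] + v[None, :] - 2.0 * C
    np.fill_diagonal(t, 0.0)
    return (t + t.T) / 2.0  # enforce exact symmetry


def _solve_basis_variances(t: np.ndarray, excluded: np.ndarray) -> np.ndarray:
    p = t.shape[0]
    M = np.ones((p, p))
    M[excluded] = 0.0
    np.fill_diagonal(M, p - 1 - excluded.sum(axis=1))
    t_eff = np.where(excluded, 0.0, t)
    try:
        omega = np.linalg.solve(M, t_eff.sum(axis=1))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"basis-variance system singular after {int(excluded.sum() // 2)} "
            f"pair exclusions ({p} taxa)"
        ) from err
    return omega


def _rho_from_omega(omega: np.ndarray, t: np.ndarray) -> np.ndarray:
    rho = (omega[:, None] + omega[None, :] - t) / (
        2.0 * np.sqrt(np.outer(omega, omega))
    )
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def basis_correlations(t: np.ndarray, config: SparccConfig = SparccConfig()) -> np.ndarray:
    """Basis correlations from a log-ratio variance matrix.

    Solves the sparsity-approximation linear system for basis variances,
    then iteratively excludes the strongest pair with |rho| above
    ``exclusion_threshold`` (one pair per round, up to
    ``max_exclusion_rounds``) and re-solves. A non-positive solved basis
    variance means the sparsity approximation failed for that taxon: its
    variance is floored at a tiny epsilon and its off-diagonal correlations
    are reported as 0 (no evidence of association) with a logged warning —
    the clamped alternative would fabricate |rho| = 1 edges. The returned
    matrix is clamped to [-1, 1] with a unit diagonal.
    """
    t = np.asarray(t, dtype=float)
    p = t.shape[0]
    if t.shape != (p, p) or not np.allclose(t, t.T):
        raise ValueError("t must be a symmetric square matrix")
    if p < 4:
        raise ValueError(f"need >= 4 taxa, got {p}")
    excluded = np.zeros((p, p), dtype=bool)
    rho = None
    for round_ in range(config.max_exclusion_rounds + 1):
        omega = _solve_basis_variances(t, excluded)
        bad = omega <= 0
        if bad.any():
            logger.warning(
                "%d non-positive basis variances; correlations for those "
                "taxa reported as 0",
                int(bad.sum()),
            )
            omega = np.maximum(omega, _OMEGA_FLOOR)
        rho = _rho_from_omega(omega, t)
        if bad.any():
            rho[bad, :] = 0.0
            rho[:, bad] = 0.0
            np.fill_diagonal(rho, 1.0)
        if round_ == config.max_exclusion_rounds:
            break
        candidates = np.abs(rho)
        np.fill_diagonal(candidates, 0.0)
        candidates[excluded] = 0.0
        # a taxon stripped of too many partners makes the system singular;
        # stop excluding pairs that would leave fewer than 3 partners
        saturated = excluded.sum(axis=1) >= p - 4
        candidates[saturated, :] = 0.0
        candidates[:, saturated] = 0.0
        i, j = np.unravel_index(np.argmax(candidates), candidates.shape)
        if candidates[i, j] <= config.exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
    return rho


def _dirichlet_fractions(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Dirichlet posterior draw of fractions per sample (+1 pseudocount)."""
    gamma = rng.standard_gamma(counts + 1.0)
    return gamma / gamma.sum(axis=0, keepdims=True)


def _sparcc_counts(counts: np.ndarray, config: SparccConfig, rng: np.random.Generator) -> np.ndarray:
    estimates = np.empty((config.n_resamples, counts.shape[0], counts.shape[0]))
    for b in range(config.n_resamples):
        fractions = _dirichlet_fractions(counts, rng)
        estimates[b] = basis_correlations(log_ratio_variances(fractions), config)
    rho = np.median(estimates, axis=0)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def sparcc(table: OtuTable, config: SparccConfig = SparccConfig()) -> pd.DataFrame:
    """SparCC correlation matrix for an OTU table.

    Median over ``n_resamples`` Dirichlet-smoothed estimates; deterministic
    under a fixed seed. Returned as a taxa x taxa DataFrame.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    rho = _sparcc_counts(table.counts.to_numpy(dtype=float), config, rng)
    return pd.DataFrame(rho, index=table.taxa, columns=table.taxa)


def permutation_pvalues(
    table: OtuTable, rho_obs: pd.DataFrame, config: SparccConfig = SparccConfig()
) -> pd.DataFrame:
    """Permutation p-values for every taxon pair.

    Each permutation shuffles every taxon's counts across samples
    independently and re-runs the full SparCC estimate; the add-one
    estimator ``p = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + B)`` bounds
    p away from zero at ``1/(B+1)``. Diagonal set to 0 by convention.
    """
    if config.n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    counts = table.counts.to_numpy(dtype=float)
    obs = np.abs(rho_obs.to_numpy(dtype=float))
    p_taxa, n = counts.shape
    ss = np.random.SeedSequence(config.seed).spawn(2)
    rng_perm = np.random.default_rng(ss[0])
    rng_est = np.random.default_rng(ss[1])
    exceed = np.zeros_like(obs)
    for _ in range(config.n_permutations):
        order = rng_perm.random((p_taxa, n)).argsort(axis=1)
        shuffled = np.take_along_axis(counts, order, axis=1)
        rho_perm = _sparcc_counts(shuffled, config, rng_est)
        exceed += np.abs(rho_perm) >= obs
    pvals = (1.0 + exceed) / (1.0 + config.n_permutations)
    pvals = (pvals + pvals.T) / 2.0
    np.fill_diagonal(pvals, 0.0)
    return pd.DataFrame(pvals, index=rho_obs.index, columns=rho_obs.columns)


@dataclass
class CorrelationNetwork:
    """A thresholded co-occurrence network.

    ``adjacency`` is 1 exactly where |rho| >= the correlation threshold AND
    p < alpha, off-diagonal; ``edge_sign`` carries +1/-1 on retained edges
    (sign of rho) and 0 elsewhere.
    """

    taxa: list[str]
    rho: pd.DataFrame
    pval: pd.DataFrame
    adjacency: pd.DataFrame
    edge_sign: pd.DataFrame
    config: SparccConfig = field(default_factory=SparccConfig)

    @property
    def n_nodes(self) -> int:
        return len(self.taxa)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.to_numpy().sum() // 2)

    @property
    def n_positive_edges(self) -> int:
        return int((self.edge_sign.to_numpy() > 0).sum() // 2)

    @property
    def n_negative_edges(self) -> int:
        return int((self.edge_sign.to_numpy() < 0).sum() // 2)

    def degrees(self) -> pd.Series:
        return self.adjacency.sum(axis=1).astype(int)

    def to_graph(self) -> nx.Graph:
        """Unweighted graph over all taxa; edges carry rho, p, and sign."""
        g = nx.Graph()
        g.add_nodes_from(self.taxa)
        adj = self.adjacency.to_numpy()
        for i, j in zip(*np.triu_indices(len(self.taxa), k=1)):
            if adj[i, j]:
                g.add_edge(
                    self.taxa[i],
                    self.taxa[j],
                    rho=float(self.rho.iat[i, j]),
                    p=float(self.pval.iat[i, j]),
                    sign=int(np.sign(self.rho.iat[i, j])),
                )
        return g

    def edge_list(self) -> pd.DataFrame:
        rows = []
        adj = self.adjacency.to_numpy()
        for i, j in zip(*np.triu_indices(len(self.taxa), k=1)):
            if adj[i, j]:
                rows.append(
                    {
                        "source": self.taxa[i],
                        "target": self.taxa[j],
                        "rho": float(self.rho.iat[i, j]),
                        "p": float(self.pval.iat[i, j]),
                        "sign": int(np.sign(self.rho.iat[i, j])),
                    }
                )
        return pd.DataFrame(rows, columns=["source", "target", "rho", "p", "sign"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_graph(), path)


def build_network(
    rho: pd.DataFrame, pval: pd.DataFrame, config: SparccConfig = SparccConfig()
) -> CorrelationNetwork:
    """Filter correlation and p-value matrices into a co-occurrence network.

    An edge is retained iff |rho| >= ``correlation_threshold`` AND
    p < ``alpha`` (both configurable; the AND is strict — a huge rho with a
    weak p is excluded).
    """
    r = rho.to_numpy(dtype=float)
    p = pval.to_numpy(dtype=float)
    if r.shape != p.shape or r.shape[0] != r.shape[1]:
        raise ValueError("rho and pval must be conformable square matrices")
    if not (np.allclose(r, r.T) and np.allclose(p, p.T)):
        raise ValueError("rho and pval must be symmetric")
    if list(rho.index) != list(pval.index):
        raise ValueError("rho and pval taxa disagree")
    keep = (np.abs(r) >= config.correlation_threshold) & (p < config.alpha)
    np.fill_diagonal(keep, False)
    sign = np.sign(r) * keep
    taxa = list(rho.index)
    net = CorrelationNetwork(
        taxa=taxa,
        rho=rho.copy(),
        pval=pval.copy(),
        adjacency=pd.DataFrame(keep.astype(int), index=taxa, columns=taxa),
        edge_sign=pd.DataFrame(sign.astype(int), index=taxa, columns=taxa),
        config=config,
    )
    logger.info(
        "network: %d nodes, %d edges (%d positive, %d negative)",
        net.n_nodes,
        net.n_edges,
        net.n_positive_edges,
        net.n_negative_edges,
    )
    return net
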