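"""Cluster-local gamma null model for background functional impact.

Genes are grouped by Ward hierarchical clustering in the normalized
12-feature space; the number of flat clusters is ceil(G / N) for a target
cluster size N (default 3000).  Within each cluster the estimated FIS
distribution, after dropping its lowest 5% as left-tail outliers and
shifting into the positive domain if needed, is fitted by a gamma
distribution via exact maximum likelihood (Newton iteration on the profile
shape equation).  The gamma is parameterised by shape alpha and RATE beta,
i.e. density  beta^alpha / Gamma(alpha) * x^(alpha-1) * exp(-beta x).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy.cluster.hierarchy import fcluster, linkage

from .feature_space import NORMALIZED, FeatureMatrix

logger = logging.getLogger(__name__)

MIN_CLUSTER_WARN = 20  # below this, the gamma fit is noisy
MIN_CLUSTER_FIT = 3  # below this, the fit is not attempted at all


@dataclass
class ClusterAssignment:
    """Flat partition of genes into 1..n_clusters Ward clusters."""

    labels: dict[str, int]
    n_clusters: int
    genes_per_cluster_target: int

    def members(self, cluster: int) -> list[str]:
        return [g for g, c in self.labels.items() if c == cluster]

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.labels.values():
            out[c] = out.get(c, 0) + 1
        return out


@dataclass
class GammaFit:
    """Fitted gamma null for one cluster (shape/rate parameterisation)."""

    cluster: int
    alpha_hat: float
    beta_hat: float
    shift: float  # added to the cluster's values before fitting (>= 0)
    n_used: int
    truncated_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha_hat) and self.alpha_hat > 0):
            raise ValueError(f"invalid shape {self.alpha_hat}")
        if not (math.isfinite(self.beta_hat) and self.beta_hat > 0):
            raise ValueError(f"invalid rate {self.beta_hat}")


def n_clusters_for(n_genes: int, genes_per_cluster: int) -> int:
    """ceil(G / N) flat clusters for a target of N genes per cluster."""
    return max(1, math.ceil(n_genes / genes_per_cluster))


def cluster_genes(
    features: FeatureMatrix, genes_per_cluster: int = 3000
) -> ClusterAssignment:
    """Ward-linkage hierarchy on Euclidean distances, cut into ceil(G/N).

    Uses the variance-minimising Ward update on raw observations, the
    algebraically correct form of the error-sum-of-squares criterion.
    Deterministic given input order.
    """
    if features.state != NORMALIZED:
        raise ValueError("cluster_genes expects a normalized feature matrix")
    G = features.n_genes
    if G < 2:
        raise ValueError("need at least 2 genes to cluster")
    n_c = n_clusters_for(G, genes_per_cluster)
    if n_c == 1:
        labels = {g: 1 for g in features.genes}
    else:
        Z = linkage(features.values, method="ward")
        flat = fcluster(Z, t=n_c, criterion="maxclust")
        labels = dict(zip(features.genes, (int(c) for c in flat)))
        n_c = len(set(labels.values()))
    assign = ClusterAssignment(labels=labels, n_clusters=n_c,
                               genes_per_cluster_target=genes_per_cluster)
    small = {c: s for c, s in assign.sizes().items() if s < MIN_CLUSTER_WARN}
    if small:
        logger.warning("cluster_genes: small cluster(s): %s", small)
    return assign


@dataclass
class TruncatedClusterValues:
    """A cluster's estimated FISs after left-tail truncation and shifting."""

    cluster: int
    values: np.ndarray  # surviving values, shifted into (0, inf) if needed
    shift: float
    kept_genes: list[str] = field(default_factory=list)
    fittable: bool = True


def truncate_and_shift(
    estimated: dict[str, float],
    clusters: ClusterAssignment,
    truncated_fraction: float = 0.05,
) -> dict[int, TruncatedClusterValues]:
    """Per cluster: drop the floor(q*n) smallest values, then shift.

    If any surviving value is <= 0 the whole cluster is shifted by
    (-min + 0.01) so its minimum becomes exactly 0.01; otherwise shift = 0.
    Clusters left with fewer than 3 values are marked unfittable (their
    genes will get NA p-values downstream); fewer than 20 draws a warning.
    """
    out: dict[int, TruncatedClusterValues] = {}
    for c in range(1, clusters.n_clusters + 1):
        genes = [g for g in estimated if clusters.labels.get(g) == c]
        vals = np.array([estimated[g] for g in genes])
        n = len(vals)
        k = int(math.floor(truncated_fraction * n))
        order = np.argsort(vals, kind="stable")
        keep_idx = order[k:]
        kept_vals = vals[keep_idx]
        kept_genes = [genes[i] for i in keep_idx]
        shift = 0.0
        if kept_vals.size and kept_vals.min() <= 0:
            shift = -float(kept_vals.min()) + 0.01
            kept_vals = kept_vals + shift
        fittable = kept_vals.size >= MIN_CLUSTER_FIT
        if not fittable:
            logger.warning(
                "cluster %d has %d value(s) after truncation; gamma fit "
                "skipped, genes get NA p-values", c, kept_vals.size
            )
        elif kept_vals.size < MIN_CLUSTER_WARN:
            logger.warning(
                "cluster %d has only %d value(s) after truncation; the "
                "gamma fit will be noisy", c, kept_vals.size
            )
        out[c] = TruncatedClusterValues(cluster=c, values=kept_vals,
                                        shift=shift, kept_genes=kept_genes,
                                        fittable=fittable)
    return out


def fit_gamma(
    values: np.ndarray,
    *,
    cluster: int = 0,
    shift: float = 0.0,
    truncated_fraction: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> GammaFit:
    """Exact gamma MLE (shape alpha, rate beta) by Newton iteration.

    Solves the profile shape equation log(a) - digamma(a) = log(mean) -
    mean(log) starting from the method-of-moments estimate, then sets
    beta = alpha / mean.  All values must be strictly positive.
    """
    x = np.asarray(values, dtype=float)
    if x.size < MIN_CLUSTER_FIT:
        raise ValueError(f"need at least {MIN_CLUSTER_FIT} values, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("gamma fit requires strictly positive values")
    var = x.var(ddof=1)
    if var == 0:
        raise ValueError("degenerate cluster: all values identical")
    mean = x.mean()
    s = math.log(mean) - float(np.mean(np.log(x)))
    if s <= 0:
        raise ValueError("degenerate values: log-mean inequality violated")

    a = mean * mean / var  # method-of-moments start
    converged = False
    for _ in range(max_iter):
        g = math.log(a) - special.digamma(a) - s
        if abs(g) < tol:
            converged = True
            break
        gprime = 1.0 / a - special.polygamma(1, a)
        a_new = a - g / gprime
        if a_new <= 0:
            a_new = a / 2.0
        a = a_new
    if not converged:
        raise RuntimeError(
            f"gamma MLE did not converge after {max_iter} iterations "
            f"(shape {a:.6g}, residual {g:.3g}, n={x.size})"
        )
    return GammaFit(cluster=cluster, alpha_hat=float(a),
                    beta_hat=float(a / mean), shift=shift, n_used=int(x.size),
                    truncated_fraction=truncated_fraction)


def fit_cluster_nulls(
    estimated: dict[str, float],
    clusters: ClusterAssignment,
    truncated_fraction: float = 0.05,
) -> dict[int, GammaFit]:
    """Truncate, shift and gamma-fit every fittable cluster."""
    fits: dict[int, GammaFit] = {}
    for c, tv in truncate_and_shift(estimated, clusters,
                                    truncated_fraction).items():
        if not tv.fittable:
            continue
        fits[c] = fit_gamma(tv.values, cluster=c, shift=tv.shift,
                            truncated_fraction=truncated_fraction)
    return fits


def write_clusters(clusters: ClusterAssignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcluster\n")
        for g, c in clusters.labels.items():
            fh.write(f"{g}\t{c}\n")


def write_fits(fits: dict[int, GammaFit], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster\talpha\tbeta\tshift\tn_used\n")
        for c in sorted(fits):
            f = fits[c]
            fh.write(f"{c}\t{f.alpha_hat!r}\t{f.beta_hat!r}\t{f.shift!r}\t"
                     f"{f.n_used}\n")
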