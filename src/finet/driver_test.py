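"""Significance testing of observed gene FIS against cluster gamma nulls.

A gene's p-value is the upper tail of its cluster's fitted gamma at the
observed FIS; genes with observed FIS <= 0 get p = 1 outright.  q-values
come from Benjamini-Hochberg, applied within each cluster by default (a
global variant is available), and drivers are the genes with q <= 0.05.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .background_model import ClusterAssignment, GammaFit
from .fis_scoring import GeneFISProfile

logger = logging.getLogger(__name__)

PER_CLUSTER = "per_cluster"
GLOBAL = "global"


def gene_pvalue(observed_fis: float, fit: GammaFit) -> float:
    """Upper-tail gamma probability of the observed FIS.

    Genes with non-positive observed FIS are outside the gamma domain and
    by construction cannot show positive selection; they get p = 1.
    """
    if observed_fis <= 0:
        return 1.0
    return float(stats.gamma.sf(observed_fis, fit.alpha_hat,
                                scale=1.0 / fit.beta_hat))


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg q-values; NaN entries pass through untouched.

    NaN p-values are excluded from the number of tests m.  Any finite value
    outside [0, 1] is fatal.
    """
    p = np.asarray(pvalues, dtype=float)
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if finite.any():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def call_drivers(
    profiles: Mapping[str, GeneFISProfile],
    fits: Mapping[int, GammaFit],
    clusters: ClusterAssignment,
    estimated: Mapping[str, float],
    alpha_fdr: float = 0.05,
    scope: str = PER_CLUSTER,
    apply_shift: bool = False,
) -> pd.DataFrame:
    """Build the per-gene driver call table.

    Every clustered gene is tested: observed FIS from its profile (0 if the
    gene carries no mutations), p from its cluster's gamma null, q by BH
    within the chosen scope, driver flag at q <= ``alpha_fdr``.  Genes in
    clusters without a valid fit get NA p/q and are never called.

    ``apply_shift`` adds the cluster's domain shift to the observed FIS
    before the tail integral (off by default: the test statistic is the
    observed FIS as-is).
    """
    if scope not in (PER_CLUSTER, GLOBAL):
        raise ValueError(f"unknown BH scope {scope!r}")
    genes = list(clusters.labels)
    rows = []
    n_unfit = 0
    for g in genes:
        c = clusters.labels[g]
        prof = profiles.get(g)
        obs = prof.observed_fis if prof is not None else 0.0
        est = estimated.get(g, np.nan)
        fit = fits.get(c)
        if fit is None:
            n_unfit += 1
            p = np.nan
        else:
            stat = obs + fit.shift if apply_shift else obs
            p = gene_pvalue(stat, fit)
        rows.append((g, c, obs, est, p))
    if n_unfit:
        logger.warning(
            "call_drivers: %d gene(s) in unfittable cluster(s); p=q=NA",
            n_unfit,
        )
    table = pd.DataFrame(
        rows, columns=["gene", "cluster", "observed_fis", "estimated_fis",
                       "p_value"],
    )
    q = np.full(len(table), np.nan)
    if scope == GLOBAL:
        q = bh_qvalues(table["p_value"].to_numpy())
    else:
        for c in table["cluster"].unique():
            idx = table.index[table["cluster"] == c]
            q[idx] = bh_qvalues(table.loc[idx, "p_value"].to_numpy())
    table["q_value"] = q
    table["is_driver"] = (table["q_value"] <= alpha_fdr).fillna(False)
    return table


def write_calls(table: pd.DataFrame, path) -> None:
    """Driver call TSV sorted by q then p."""
    out = table.sort_values(["q_value", "p_value", "gene"],
                            na_position="last")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def driver_genes(table: pd.DataFrame) -> set[str]:
    return set(table.loc[table["is_driver"], "gene"])
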