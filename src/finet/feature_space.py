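"""The gene x 12 multi-omics feature matrix.

Nine "static" covariates (expression, replication timing, chromatin
compartment, gene length, missense constraint, network hubness, regulatory
role, copy-number alteration, methylation) come from an external TSV; the
remaining three (total mutation count, deleterious mutation count, FIS
standard deviation) are derived from the cohort's own MAF.

Missing static values are imputed by a K-nearest-neighbour mean: distances
between genes are squared Euclidean over the features present in *both*
genes, and the neighbour pool for a missing cell (gene g, feature k) is the
K closest genes that carry feature k.  Imputation runs on the raw values;
z-normalisation (zero mean, unit sample s.d. per column) comes after.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STATIC_FEATURES = (
    "expression",
    "replication_timing",
    "hic",
    "gene_length",
    "constraint",
    "hubness",
    "regulatory_role",
    "cna",
    "methylation",
)
MAF_FEATURES = ("total_mutations", "deleterious_mutations", "fis_std")
FEATURE_NAMES = STATIC_FEATURES + MAF_FEATURES
N_FEATURES = len(FEATURE_NAMES)

RAW = "raw"
IMPUTED = "imputed"
NORMALIZED = "normalized"


@dataclass
class FeatureMatrix:
    """Genes x 12 feature values with an explicit missingness mask.

    ``state`` tracks the processing stage; ``missing_mask`` always refers to
    the *original* missingness, so imputed cells remain identifiable.  After
    :func:`normalize`, the column means/s.d.s used are stored for exact
    de-normalisation.
    """

    genes: list[str]
    values: np.ndarray  # (G, 12), NaN where missing in raw state
    missing_mask: np.ndarray  # (G, 12) bool, True = originally missing
    state: str = RAW
    norm_means: np.ndarray | None = field(default=None, repr=False)
    norm_stds: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != (len(self.genes), N_FEATURES):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.genes)}, {N_FEATURES})"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape mismatch")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes,
                            columns=list(FEATURE_NAMES))

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t", float_format="%.10g")


def load_static_features(path: str | Path) -> pd.DataFrame:
    """Read the 9-column static covariate TSV (first column = gene symbol).

    Empty cells are missing.  Duplicate gene rows are fatal.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing_cols = [c for c in STATIC_FEATURES if c not in df.columns]
    if missing_cols:
        raise ValueError(
            f"{path}: missing feature column(s): {', '.join(missing_cols)}"
        )
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene row(s): {dups}")
    return df[list(STATIC_FEATURES)].astype(float)


def assemble(
    static: pd.DataFrame,
    maf_features: dict[str, tuple[float, float, float]],
) -> FeatureMatrix:
    """Combine static covariates with MAF-derived counts into a raw matrix.

    The gene universe is the union of both sources, static-table order first
    and MAF-only genes appended in sorted order.  Genes without a static row
    are missing in columns 1-9; genes absent from the MAF get (0, 0, 0) in
    columns 10-12.
    """
    static_genes = list(static.index.astype(str))
    extra = sorted(set(maf_features) - set(static_genes))
    genes = static_genes + extra

    values = np.full((len(genes), N_FEATURES), np.nan)
    values[: len(static_genes), :9] = static.to_numpy(dtype=float)
    for i, g in enumerate(genes):
        values[i, 9:] = maf_features.get(g, (0.0, 0.0, 0.0))
    mask = np.isnan(values)
    return FeatureMatrix(genes=genes, values=values, missing_mask=mask,
                         state=RAW)


def _pairwise_copresent_sqdist(values: np.ndarray,
                               present: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance over features present in both genes.

    Pairs sharing no feature get +inf (an empty sum would spuriously read
    as distance 0).  The diagonal is +inf so a gene is never its own
    neighbour.
    """
    a = np.where(present, values, 0.0)
    a2 = a * a
    p = present.astype(float)
    d = a2 @ p.T + p @ a2.T - 2.0 * (a @ a.T)
    np.maximum(d, 0.0, out=d)  # guard tiny negative round-off
    co = p @ p.T
    d[co == 0] = np.inf
    np.fill_diagonal(d, np.inf)
    return d


def impute_missing(m: FeatureMatrix, K: int = 100) -> FeatureMatrix:
    """Fill each missing cell with the mean over the K nearest carriers.

    For missing cell (g, k) the candidates are genes with feature k present;
    the K nearest by co-present squared Euclidean distance from g are
    averaged.  Ties at the K-th slot break by input gene order.  Fewer than
    K candidates -> use all, with a warning.  A gene with all features
    missing is fatal.
    """
    if m.state != RAW:
        raise ValueError(f"impute_missing expects a raw matrix, got {m.state}")
    present = ~np.isnan(m.values)
    all_missing = np.where(~present.any(axis=1))[0]
    if all_missing.size:
        raise ValueError(
            "gene(s) with all features missing: "
            + ", ".join(m.genes[i] for i in all_missing)
        )
    values = m.values.copy()
    if present.all():
        return FeatureMatrix(m.genes, values, m.missing_mask.copy(),
                             state=IMPUTED)

    dist = _pairwise_copresent_sqdist(m.values, present)
    short_pool = 0
    for k in range(N_FEATURES):
        carriers = np.where(present[:, k])[0]
        targets = np.where(~present[:, k])[0]
        if targets.size == 0:
            continue
        if carriers.size == 0:
            raise ValueError(
                f"feature {FEATURE_NAMES[k]!r} has no observed values"
            )
        for g in targets:
            d = dist[g, carriers]
            finite = np.isfinite(d)
            pool = carriers[finite]
            dpool = d[finite]
            if pool.size == 0:
                raise ValueError(
                    f"no usable neighbours for gene {m.genes[g]} "
                    f"feature {FEATURE_NAMES[k]!r}"
                )
            if pool.size < K:
                short_pool += 1
                chosen = pool
            else:
                # stable sort on distance keeps input order among ties
                order = np.argsort(dpool, kind="stable")[:K]
                chosen = pool[order]
            values[g, k] = m.values[chosen, k].mean()
    if short_pool:
        logger.warning(
            "impute_missing: %d cell(s) had fewer than K=%d candidate "
            "neighbours; used all available", short_pool, K
        )
    return FeatureMatrix(m.genes, values, m.missing_mask.copy(),
                         state=IMPUTED)


def normalize(m: FeatureMatrix) -> FeatureMatrix:
    """Center each column and scale to unit sample standard deviation."""
    if m.state != IMPUTED:
        raise ValueError(f"normalize expects an imputed matrix, got {m.state}")
    if np.isnan(m.values).any():
        raise ValueError("matrix still contains missing values")
    means = m.values.mean(axis=0)
    stds = m.values.std(axis=0, ddof=1)
    zero = np.where(stds == 0)[0]
    if zero.size:
        raise ValueError(
            "zero-variance feature(s): "
            + ", ".join(FEATURE_NAMES[i] for i in zero)
        )
    z = (m.values - means) / stds
    return FeatureMatrix(m.genes, z, m.missing_mask.copy(), state=NORMALIZED,
                         norm_means=means, norm_stds=stds)


def denormalize(m: FeatureMatrix) -> np.ndarray:
    """Invert :func:`normalize` using the stored column statistics."""
    if m.state != NORMALIZED or m.norm_means is None:
        raise ValueError("matrix is not normalized")
    return m.values * m.norm_stds + m.norm_means
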