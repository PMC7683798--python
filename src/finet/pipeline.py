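"""End-to-end orchestration: read -> score -> features -> train -> cluster
-> fit -> test -> report.

Every tunable surfaces in :class:`PipelineConfig` with the method's default
values (K = 100 imputation neighbours, N = 3000 genes per cluster, 100
hidden units, 10 training epochs, 5% left-tail truncation, BH within each
cluster at q <= 0.05).  A run is a pure function of (input files, config,
seed); stage outputs are written individually so any stage can be re-loaded
and audited.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import background_model, driver_test, feature_space, fis_regressor
from . import fis_scoring, maf_io, metrics

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    maf: str = ""
    fis_table: str = ""
    features: str = ""
    output_dir: str = "finet_out"
    reference_lists: dict[str, str] = field(default_factory=dict)
    effect_dictionary: str | None = None
    K: int = 100
    N: int = 3000
    hidden_units: int = 100
    epochs: int = 10
    learning_rate: float = 0.01
    batch_size: int = 4
    alpha_fdr: float = 0.05
    truncation: float = 0.05
    bh_scope: str = driver_test.PER_CLUSTER
    output_activation: str = fis_regressor.LINEAR
    apply_shift: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("maf", "fis_table", "features"):
            p = getattr(self, name)
            if not p:
                raise FileNotFoundError(f"config: {name} path not set")
            if not Path(p).exists():
                raise FileNotFoundError(f"config: {name} path not found: {p}")
        if not 0 <= self.truncation < 1:
            raise ValueError("truncation must be in [0, 1)")
        if not 0 < self.alpha_fdr <= 1:
            raise ValueError("alpha_fdr must be in (0, 1]")


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    calls: pd.DataFrame
    drivers: set[str]
    profiles: dict
    annotated: list
    estimated: dict[str, float]
    clusters: background_model.ClusterAssignment
    fits: dict[int, background_model.GammaFit]
    model: fis_regressor.RegressionModel
    features: feature_space.FeatureMatrix
    metrics: dict[str, float]
    manifest: dict


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write all stage outputs.

    Raises with a stage-named message on any fatal error.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)
        return name

    manifest: dict = {"config": dataclasses.asdict(config),
                      "seed": config.seed, "version": __version__,
                      "stages": {}}

    current = stage("read_maf")
    try:
        effect_dict = (
            maf_io.load_effect_dictionary(config.effect_dictionary)
            if config.effect_dictionary else maf_io.DEFAULT_EFFECT_DICTIONARY
        )
        records, skipped = maf_io.read_maf(config.maf, effect_dict)
        manifest["stages"][current] = {"records": len(records),
                                       "skipped": skipped}

        current = stage("load_fis_table")
        table = maf_io.load_fis_table(config.fis_table)
        manifest["stages"][current] = {"entries": len(table)}

        current = stage("annotate_fis")
        annotated = fis_scoring.annotate_fis(records, table)
        by_source: dict[str, int] = {}
        for a in annotated:
            by_source[a.fis_source] = by_source.get(a.fis_source, 0) + 1
        fis_scoring.write_annotated(annotated, out / "annotated_mutations.tsv")
        manifest["stages"][current] = by_source

        current = stage("observed_gene_fis")
        profiles = fis_scoring.observed_gene_fis(annotated)
        fis_scoring.write_profiles(profiles, out / "gene_profiles.tsv")
        manifest["stages"][current] = {"genes_with_mutations": len(profiles)}

        current = stage("assemble_features")
        static = feature_space.load_static_features(config.features)
        universe = list(static.index.astype(str))
        universe += sorted(set(profiles) - set(universe))
        maf_feats = fis_scoring.maf_derived_features(profiles, universe)
        raw = feature_space.assemble(static, maf_feats)
        manifest["stages"][current] = {"genes": raw.n_genes,
                                       "missing_cells":
                                           int(raw.missing_mask.sum())}

        current = stage("impute_missing")
        imputed = feature_space.impute_missing(raw, K=config.K)

        current = stage("normalize")
        normalized = feature_space.normalize(imputed)
        normalized.write_tsv(out / "feature_matrix.tsv")

        current = stage("train_regressor")
        targets = {g: (profiles[g].observed_fis if g in profiles else 0.0)
                   for g in normalized.genes}
        model = fis_regressor.train(
            normalized, targets, seed=config.seed, epochs=config.epochs,
            hidden_units=config.hidden_units,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            output_activation=config.output_activation,
        )
        model.save(out / "model.json")
        manifest["stages"][current] = {
            "final_loss": model.training_loss_trace[-1]
        }

        current = stage("predict")
        estimated = fis_regressor.predict(model, normalized)
        fis_regressor.write_predictions(estimated, out / "predictions.tsv")

        current = stage("cluster_genes")
        clusters = background_model.cluster_genes(normalized, config.N)
        background_model.write_clusters(clusters, out / "clusters.tsv")
        manifest["stages"][current] = {
            "n_clusters": clusters.n_clusters,
            "sizes": clusters.sizes(),
        }

        current = stage("fit_gamma_nulls")
        fits = background_model.fit_cluster_nulls(
            estimated, clusters, truncated_fraction=config.truncation
        )
        background_model.write_fits(fits, out / "gamma_fits.tsv")
        manifest["stages"][current] = {
            c: {"alpha": f.alpha_hat, "beta": f.beta_hat, "shift": f.shift,
                "n_used": f.n_used}
            for c, f in fits.items()
        }

        current = stage("call_drivers")
        calls = driver_test.call_drivers(
            profiles, fits, clusters, estimated,
            alpha_fdr=config.alpha_fdr, scope=config.bh_scope,
            apply_shift=config.apply_shift,
        )
        driver_test.write_calls(calls, out / "driver_calls.tsv")
        drivers = driver_test.driver_genes(calls)
        maf_io.write_gene_list(drivers, out / "drivers.txt")
        manifest["stages"][current] = {"n_drivers": len(drivers)}

        current = stage("metrics")
        references = {
            name: maf_io.load_gene_list(path)
            for name, path in config.reference_lists.items()
        }
        run_metrics: dict[str, float] = {}
        if drivers:
            run_metrics = metrics.summarize(drivers, records, annotated,
                                            references)
        with open(out / "metrics.tsv", "w") as fh:
            fh.write("metric\tvalue\n")
            for k, v in run_metrics.items():
                fh.write(f"{k}\t{v!r}\n")
        manifest["stages"][current] = run_metrics
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return PipelineResult(
        calls=calls, drivers=drivers, profiles=profiles, annotated=annotated,
        estimated=estimated, clusters=clusters, fits=fits, model=model,
        features=normalized, metrics=run_metrics, manifest=manifest,
    )
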