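"""Per-mutation FIS resolution and gene-level aggregation.

Every mutation receives a functional impact score by a three-step rule:

1. direct lookup in the precomputed score table;
2. otherwise the cohort-wide mean of looked-up scores sharing the mutation's
   effect class (effect-mean imputation);
3. otherwise a fixed ordinal fallback encoding the expected protein impact
   of the effect class: silent 0 < non-coding 1 < non-silent 2 < null 3.

Gene-level observed FIS is the plain sum of mutation scores over the pooled
cohort; per-sample sums feed the FIS standard-deviation feature.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .maf_io import (
    EFFECTS,
    NON_SILENT,
    NULL,
    FISTable,
    MutationRecord,
)

LOOKUP = "lookup"
EFFECT_MEAN = "effect_mean"
FIXED_FALLBACK = "fixed_fallback"

#: Ordinal fallback scores when an effect class has no looked-up scores.
FALLBACK_FIS = {"silent": 0.0, "non-coding": 1.0, "non-silent": 2.0,
                "null": 3.0}

DELETERIOUS_EFFECTS = frozenset({NON_SILENT, NULL})


@dataclass(frozen=True)
class AnnotatedMutation:
    """A mutation with its resolved FIS and the provenance of that score."""

    record: MutationRecord
    effect: str
    fis: float
    fis_source: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.fis):
            raise ValueError(f"non-finite FIS for {self.record.gene}")
        if self.fis_source == FIXED_FALLBACK and self.fis not in (0, 1, 2, 3):
            raise ValueError("fixed fallback FIS must be one of 0,1,2,3")


@dataclass
class GeneFISProfile:
    """Aggregated FIS view of one gene across the cohort."""

    gene: str
    observed_fis: float
    per_sample_fis: dict[str, float] = field(default_factory=dict)
    n_mutations: int = 0
    n_deleterious: int = 0
    fis_std: float = 0.0


def annotate_fis(
    mutations: Iterable[MutationRecord], table: FISTable
) -> list[AnnotatedMutation]:
    """Resolve a FIS for every mutation (lookup -> effect mean -> fallback).

    Effect means are computed over the whole cohort's looked-up scores per
    effect class, so the imputation is idempotent: re-annotating the same
    records against the same table reproduces identical scores.
    """
    mutations = list(mutations)
    for m in mutations:
        if m.effect is None:
            raise ValueError(f"mutation in {m.gene} has no effect attached")

    looked_up: dict[MutationRecord, float] = {}
    by_effect_scores: dict[str, list[float]] = {e: [] for e in EFFECTS}
    for m in mutations:
        score = table.lookup_record(m)
        if score is not None:
            looked_up[m] = score
            by_effect_scores[m.effect].append(score)

    effect_means = {
        e: sum(v) / len(v) for e, v in by_effect_scores.items() if v
    }

    annotated = []
    for m in mutations:
        if m in looked_up:
            annotated.append(
                AnnotatedMutation(m, m.effect, looked_up[m], LOOKUP)
            )
        elif m.effect in effect_means:
            annotated.append(
                AnnotatedMutation(m, m.effect, effect_means[m.effect],
                                  EFFECT_MEAN)
            )
        else:
            annotated.append(
                AnnotatedMutation(m, m.effect, FALLBACK_FIS[m.effect],
                                  FIXED_FALLBACK)
            )
    return annotated


def observed_gene_fis(
    annotated: Iterable[AnnotatedMutation],
) -> dict[str, GeneFISProfile]:
    """Sum mutation FISs to gene level, pooled over the cohort.

    ``fis_std`` is the sample standard deviation of the per-sample FIS sums,
    restricted to samples in which the gene is mutated; a gene mutated in a
    single sample gets 0.
    """
    profiles: dict[str, GeneFISProfile] = {}
    for a in annotated:
        g = a.record.gene
        prof = profiles.get(g)
        if prof is None:
            prof = profiles[g] = GeneFISProfile(gene=g, observed_fis=0.0)
        prof.observed_fis += a.fis
        prof.per_sample_fis[a.record.sample] = (
            prof.per_sample_fis.get(a.record.sample, 0.0) + a.fis
        )
        prof.n_mutations += 1
        if a.effect in DELETERIOUS_EFFECTS:
            prof.n_deleterious += 1
    for prof in profiles.values():
        vals = list(prof.per_sample_fis.values())
        if len(vals) >= 2:
            mean = sum(vals) / len(vals)
            prof.fis_std = math.sqrt(
                sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
            )
        else:
            prof.fis_std = 0.0
    return profiles


def maf_derived_features(
    profiles: Mapping[str, GeneFISProfile], genes: Iterable[str]
) -> dict[str, tuple[float, float, float]]:
    """Features 10-12 of the gene feature matrix.

    Per gene: (total mutation count, deleterious mutation count, sample s.d.
    of per-sample FIS sums).  Genes absent from the MAF get (0, 0, 0).
    """
    out = {}
    for g in genes:
        prof = profiles.get(g)
        if prof is None:
            out[g] = (0.0, 0.0, 0.0)
        else:
            out[g] = (float(prof.n_mutations), float(prof.n_deleterious),
                      prof.fis_std)
    return out


# --- audit exports ---------------------------------------------------------

_ANNOT_COLUMNS = ("gene", "chrom", "start", "end", "variant_classification",
                  "ref_allele", "alt_allele", "sample", "effect", "fis",
                  "fis_source")


def write_annotated(
    annotated: Iterable[AnnotatedMutation], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_ANNOT_COLUMNS)
        for a in annotated:
            r = a.record
            w.writerow([r.gene, r.chrom, r.start, r.end,
                        r.variant_classification, r.ref_allele, r.alt_allele,
                        r.sample, a.effect, repr(a.fis), a.fis_source])


def read_annotated(path: str | Path) -> list[AnnotatedMutation]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rec = MutationRecord(
                gene=row["gene"], chrom=row["chrom"], start=int(row["start"]),
                end=int(row["end"]),
                variant_classification=row["variant_classification"],
                ref_allele=row["ref_allele"], alt_allele=row["alt_allele"],
                sample=row["sample"], effect=row["effect"],
            )
            out.append(AnnotatedMutation(rec, row["effect"],
                                         float(row["fis"]),
                                         row["fis_source"]))
    return out


def write_profiles(
    profiles: Mapping[str, GeneFISProfile], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "observed_fis", "n_mutations", "n_deleterious",
                    "fis_std"])
        for g in sorted(profiles):
            p = profiles[g]
            w.writerow([p.gene, repr(p.observed_fis), p.n_mutations,
                        p.n_deleterious, repr(p.fis_std)])
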