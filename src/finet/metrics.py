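"""Evaluation statistics for a called driver-gene set.

Coverage: fraction of patients carrying at least one mutation in the set.
Deleterious ratio: per gene, the fraction of its mutations that are
non-silent or null.  Precision: overlap fraction of the calls with a
reference list (Cancer Gene Census / Network of Cancer Genes style), defined
as 0 when fewer than three genes were called.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Set

from .fis_scoring import DELETERIOUS_EFFECTS, AnnotatedMutation
from .maf_io import MutationRecord


def coverage(gene_set: Set[str], mutations: Iterable[MutationRecord]) -> float:
    """|patients with >= 1 mutation in the set| / |all patients|."""
    patients: set[str] = set()
    covered: set[str] = set()
    for m in mutations:
        patients.add(m.sample)
        if m.gene in gene_set:
            covered.add(m.sample)
    if not patients:
        raise ValueError("empty mutation list: coverage undefined (m = 0)")
    return len(covered) / len(patients)


def deleterious_ratio(
    gene: str, annotated: Iterable[AnnotatedMutation]
) -> float:
    """(non-silent + null mutations) / total mutations of the gene."""
    total = 0
    deleterious = 0
    for a in annotated:
        if a.record.gene != gene:
            continue
        total += 1
        if a.effect in DELETERIOUS_EFFECTS:
            deleterious += 1
    if total == 0:
        return math.nan
    return deleterious / total


def mean_deleterious_ratio(
    genes: Set[str], annotated: Iterable[AnnotatedMutation]
) -> float:
    """Average deleterious ratio over genes with >= 1 mutation."""
    annotated = list(annotated)
    ratios = [deleterious_ratio(g, annotated) for g in genes]
    ratios = [r for r in ratios if not math.isnan(r)]
    if not ratios:
        return math.nan
    return sum(ratios) / len(ratios)


def precision_vs_list(
    called: Set[str], reference: Set[str], min_calls: int = 3
) -> float:
    """|called ∩ reference| / |called|, or 0 for fewer than min_calls calls."""
    if len(called) < min_calls:
        return 0.0
    return len(called & reference) / len(called)


def summarize(
    called: Set[str],
    mutations: Iterable[MutationRecord],
    annotated: Iterable[AnnotatedMutation],
    references: Mapping[str, Set[str]] | None = None,
) -> dict[str, float]:
    """One-stop metrics block for a finished run."""
    out: dict[str, float] = {
        "n_drivers": float(len(called)),
        "coverage": coverage(called, mutations),
        "mean_deleterious_ratio": mean_deleterious_ratio(called, annotated),
    }
    for name, ref in (references or {}).items():
        out[f"precision_{name}"] = precision_vs_list(called, ref)
    return out
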