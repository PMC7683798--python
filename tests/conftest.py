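"""Shared fixtures: tiny hand-written cohort files and record builders."""

from __future__ import annotations

import numpy as np
import pytest

from finet.maf_io import MutationRecord

MAF_HEADER = ("Hugo_Symbol\tChromosome\tStart_Position\tEnd_Position\t"
              "Variant_Classification\tReference_Allele\tTumor_Seq_Allele\t"
              "Tumor_Sample_Barcode\n")


def write_maf(path, rows):
    """rows: iterable of 8-tuples matching the header."""
    with open(path, "w") as fh:
        fh.write(MAF_HEADER)
        for r in rows:
            fh.write("\t".join(str(v) for v in r) + "\n")
    return path


def make_record(gene="TP53", chrom="17", start=100, end=100,
                classification="Missense_Mutation", ref="G", alt="A",
                sample="S1", effect="non-silent"):
    return MutationRecord(gene=gene, chrom=chrom, start=start, end=end,
                          variant_classification=classification,
                          ref_allele=ref, alt_allele=alt, sample=sample,
                          effect=effect)


@pytest.fixture
def toy_maf(tmp_path):
    """Three mutations covering silent / non-silent / null effects."""
    return write_maf(
        tmp_path / "toy.maf",
        [
            ("TP53", "17", 7577120, 7577120, "Silent", "C", "T", "S1"),
            ("KRAS", "12", 25398284, 25398284, "Missense_Mutation", "C", "A",
             "S2"),
            ("PTEN", "10", 89692905, 89692905, "Nonsense_Mutation", "G", "T",
             "S1"),
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
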