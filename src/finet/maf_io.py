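"""Readers and writers for MAF mutation files, FIS lookup tables, effect
dictionaries and plain gene lists.

The mutation container is intentionally minimal: only the eight MAF columns
that the downstream scoring needs are retained.  Chromosome labels are
normalized to the prefix-free form ("chr7" -> "7") so that MAF records and
FIS-table keys always agree.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

# Mutation effect labels, ordered by increasing expected protein impact.
SILENT = "silent"
NON_CODING = "non-coding"
NON_SILENT = "non-silent"
NULL = "null"
EFFECTS = (SILENT, NON_CODING, NON_SILENT, NULL)

ESSENTIAL_COLUMNS = (
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "End_Position",
    "Variant_Classification",
    "Reference_Allele",
    "Tumor_Seq_Allele",
    "Tumor_Sample_Barcode",
)


class MafFormatError(ValueError):
    """The MAF file violates the expected layout (e.g. a missing column)."""


class EffectDictionaryError(ValueError):
    """A variant classification has no entry in the effect dictionary."""


class FISTableError(ValueError):
    """The FIS lookup table could not be parsed."""


def normalize_chrom(chrom: str) -> str:
    """Strip any 'chr' prefix and upper-case X/Y/M labels."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper() if c.lower() in ("x", "y", "m", "mt") else c


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call (one MAF data row).

    Coordinates are 1-based inclusive, per the MAF standard.  ``effect`` is
    attached at read time from an :class:`EffectDictionary` and is ``None``
    only for records constructed by hand.
    """

    gene: str
    chrom: str
    start: int
    end: int
    variant_classification: str
    ref_allele: str
    alt_allele: str
    sample: str
    effect: str | None = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if not self.sample:
            raise ValueError("sample barcode must be non-empty")
        if self.start > self.end:
            raise ValueError(
                f"start {self.start} > end {self.end} for {self.gene}"
            )

    def fis_key(self) -> tuple[str, int, str, str]:
        """Lookup key into a :class:`FISTable` (chrom, pos, ref, alt)."""
        return (
            normalize_chrom(self.chrom),
            self.start,
            self.ref_allele.upper(),
            self.alt_allele.upper(),
        )


class EffectDictionary:
    """Maps MAF variant classifications to the four effect classes.

    Lookups are case-sensitive on the classification string; an unmapped
    classification raises :class:`EffectDictionaryError` rather than
    defaulting silently.
    """

    def __init__(self, mapping: Mapping[str, str]):
        bad = {c: e for c, e in mapping.items() if e not in EFFECTS}
        if bad:
            raise ValueError(f"invalid effect labels: {bad}")
        self._mapping = dict(mapping)

    def __getitem__(self, classification: str) -> str:
        try:
            return self._mapping[classification]
        except KeyError:
            raise EffectDictionaryError(
                f"variant classification not in effect dictionary: "
                f"{classification!r}"
            ) from None

    def __contains__(self, classification: str) -> bool:
        return classification in self._mapping

    def items(self):
        return self._mapping.items()


#: Default classification -> effect table covering the standard TCGA MAF
#: vocabulary.  User-overridable via :func:`load_effect_dictionary`.
DEFAULT_EFFECT_DICTIONARY = EffectDictionary(
    {
        "Silent": SILENT,
        "Missense_Mutation": NON_SILENT,
        "In_Frame_Del": NON_SILENT,
        "In_Frame_Ins": NON_SILENT,
        "Nonstop_Mutation": NON_SILENT,
        "Nonsense_Mutation": NULL,
        "Splice_Site": NULL,
        "Frame_Shift_Del": NULL,
        "Frame_Shift_Ins": NULL,
        "Translation_Start_Site": NULL,
        "3'UTR": NON_CODING,
        "5'UTR": NON_CODING,
        "Intron": NON_CODING,
        "RNA": NON_CODING,
        "IGR": NON_CODING,
        "5'Flank": NON_CODING,
        "3'Flank": NON_CODING,
    }
)


def load_effect_dictionary(path: str | Path) -> EffectDictionary:
    """Read a 2-column TSV (variant_classification, effect)."""
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        for line_no, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(
                    f"{path}: line {line_no}: expected 2 columns"
                )
            mapping[row[0].strip()] = row[1].strip()
    return EffectDictionary(mapping)


def read_maf(
    path: str | Path,
    effect_dict: EffectDictionary = DEFAULT_EFFECT_DICTIONARY,
) -> tuple[list[MutationRecord], int]:
    """Read a MAF file and attach mutation effects.

    Returns ``(records, n_skipped)`` where ``n_skipped`` counts data rows
    dropped because an essential field was empty.  A missing essential
    *column* is a :class:`MafFormatError`; any variant classification absent
    from ``effect_dict`` is collected and raised as a single
    :class:`EffectDictionaryError`.
    """
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t")
                if r and not r[0].startswith("#")]
    if not rows:
        raise MafFormatError(f"{path}: no header row")
    header = [h.strip() for h in rows[0]]
    lower = [h.lower() for h in header]
    col_idx: dict[str, int] = {}
    missing = []
    for col in ESSENTIAL_COLUMNS:
        try:
            col_idx[col] = lower.index(col.lower())
        except ValueError:
            missing.append(col)
    if missing:
        raise MafFormatError(
            f"{path}: missing essential column(s): {', '.join(missing)}"
        )

    records: list[MutationRecord] = []
    skipped = 0
    unmapped: set[str] = set()
    for row in rows[1:]:
        fields = {}
        ok = True
        for col, idx in col_idx.items():
            val = row[idx].strip() if idx < len(row) else ""
            if not val:
                ok = False
                break
            fields[col] = val
        if not ok:
            skipped += 1
            continue
        classification = fields["Variant_Classification"]
        if classification not in effect_dict:
            unmapped.add(classification)
            continue
        records.append(
            MutationRecord(
                gene=fields["Hugo_Symbol"],
                chrom=normalize_chrom(fields["Chromosome"]),
                start=int(fields["Start_Position"]),
                end=int(fields["End_Position"]),
                variant_classification=classification,
                ref_allele=fields["Reference_Allele"],
                alt_allele=fields["Tumor_Seq_Allele"],
                sample=fields["Tumor_Sample_Barcode"],
                effect=effect_dict[classification],
            )
        )
    if unmapped:
        raise EffectDictionaryError(
            "variant classifications not in effect dictionary: "
            + ", ".join(sorted(unmapped))
        )
    if skipped:
        logger.info("read_maf: skipped %d row(s) with empty fields", skipped)
    return records, skipped


def write_maf(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write records back out as a minimal 8-column MAF."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ESSENTIAL_COLUMNS)
        for r in records:
            w.writerow(
                [r.gene, r.chrom, r.start, r.end, r.variant_classification,
                 r.ref_allele, r.alt_allele, r.sample]
            )


class FISTable:
    """Per-mutation functional impact scores keyed by (chrom, pos, ref, alt).

    Emulates a MutationAssessor-style precomputed score table; scores are
    unitless functional-impact values.
    """

    def __init__(self, entries: Mapping[tuple[str, int, str, str], float]):
        self._entries = dict(entries)

    def lookup(self, chrom: str, pos: int, ref: str, alt: str) -> float | None:
        return self._entries.get(
            (normalize_chrom(chrom), int(pos), ref.upper(), alt.upper())
        )

    def lookup_record(self, record: MutationRecord) -> float | None:
        return self._entries.get(record.fis_key())

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self._entries


def load_fis_table(path: str | Path) -> FISTable:
    """Read a 5-column TSV (chrom, pos, ref, alt, score); header optional.

    Duplicate keys keep the first occurrence (with a warning); a non-numeric
    score is a :class:`FISTableError` naming the line.
    """
    entries: dict[tuple[str, int, str, str], float] = {}
    n_dup = 0
    with open(path, newline="") as fh:
        for line_no, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 5:
                raise FISTableError(
                    f"{path}: line {line_no}: expected 5 columns, "
                    f"got {len(row)}"
                )
            if line_no == 1 and _looks_like_header(row):
                continue
            try:
                pos = int(row[1])
                score = float(row[4])
            except ValueError:
                raise FISTableError(
                    f"{path}: line {line_no}: non-numeric position or score: "
                    f"{row[1]!r}, {row[4]!r}"
                ) from None
            key = (normalize_chrom(row[0]), pos, row[2].strip().upper(),
                   row[3].strip().upper())
            if key in entries:
                n_dup += 1
                continue
            entries[key] = score
    if n_dup:
        logger.warning(
            "load_fis_table: %d duplicate key(s); kept first occurrence", n_dup
        )
    return FISTable(entries)


def _looks_like_header(row: list[str]) -> bool:
    try:
        int(row[1])
        float(row[4])
    except ValueError:
        return True
    return False


def load_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blanks ignored, whitespace stripped."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym:
                genes.add(sym)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")
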