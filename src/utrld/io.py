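"""Subject-table and definition-table I/O.

The canonical dialect is TSV (haplotype pair names contain commas), UTF-8,
"." decimal separator. One row per subject:

    subject_id  cohort  motif_1  motif_2  [utr_label_1  utr_label_2]
    [utr_allele_block_1  utr_allele_block_2]  [sHLA_G]  [inflammation]
    [biopsied]  [ihc_<cell_type> ...]  [arbitrary clinical columns ...]

``motif_i`` is the compact 8-site motif of chromosome i; the optional
``utr_label_i`` columns carry lab-resolved haplotype names and take
precedence over motif lookup (two built-in definitions share a motif, so
labels cannot always be recovered from motifs alone). The allele-block
columns give the classical alleles phased with that chromosome as
semicolon-separated ``locus*allele`` tokens, e.g.
"A*30:02;B*18:01;C*05:01;DRB1*03:01". Unknown columns are preserved as
clinical variables.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from . import histology
from .haplotypes import (
    UTRHaplotypeDefinition,
    assign_utr_haplotype,
    default_definitions,
    parse_motif,
)
from .records import Chromosome, SubjectRecord

MANDATORY_COLUMNS = ("subject_id", "cohort", "motif_1", "motif_2")
_STRUCTURAL_COLUMNS = MANDATORY_COLUMNS + (
    "utr_label_1", "utr_label_2", "utr_allele_block_1", "utr_allele_block_2",
    "sHLA_G", "inflammation", "biopsied",
)
_IHC_PREFIX = "ihc_"


class BadRowsError(ValueError):
    """Raised when one or more subject rows are malformed."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__(
            f"{len(errors)} malformed subject row(s):\n" + "\n".join(errors)
        )


def _parse_allele_block(text: str) -> dict[str, str]:
    alleles: dict[str, str] = {}
    for token in filter(None, (t.strip() for t in text.split(";"))):
        if "*" not in token:
            raise ValueError(f"allele token {token!r} is not locus*allele")
        locus, allele = token.split("*", 1)
        alleles[locus] = allele
    return alleles


def _format_allele_block(alleles: dict[str, str]) -> str:
    return ";".join(f"{locus}*{allele}" for locus, allele in sorted(alleles.items()))


def _parse_clinical(text: str) -> object:
    if text in ("True", "False"):
        return text == "True"
    try:
        return float(text)
    except ValueError:
        return text


def read_definitions(path) -> list[UTRHaplotypeDefinition]:
    """Read a haplotype-definition TSV with columns label, motif."""
    defs = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"label", "motif"} <= set(reader.fieldnames):
            raise ValueError("definition table must have columns: label, motif")
        for row in reader:
            defs.append(UTRHaplotypeDefinition(row["label"], parse_motif(row["motif"])))
    return defs


def read_subjects(
    path,
    defs: Sequence[UTRHaplotypeDefinition] | None = None,
    skip_bad: bool = False,
    floor_shlag: bool = False,
) -> tuple[list[SubjectRecord], list[str]]:
    """Read a subject TSV into validated records.

    Returns (records, error_report). Malformed rows abort the run with
    :class:`BadRowsError` unless ``skip_bad``, in which case they are
    dropped and reported. ``floor_shlag`` floors soluble HLA-G at the ELISA
    detection limit (0.6 U/mL); by default values are kept as reported.
    """
    if defs is None:
        defs = default_definitions()
    records: list[SubjectRecord] = []
    errors: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        columns = reader.fieldnames or []
        missing = [c for c in MANDATORY_COLUMNS if c not in columns]
        if missing:
            raise ValueError(f"subject table missing mandatory column(s): {missing}")
        clinical_cols = [
            c for c in columns
            if c not in _STRUCTURAL_COLUMNS and not c.startswith(_IHC_PREFIX)
        ]
        ihc_cols = [c for c in columns if c.startswith(_IHC_PREFIX)]
        for lineno, row in enumerate(reader, start=2):
            sid = row.get("subject_id", "")
            try:
                records.append(
                    _parse_row(row, defs, clinical_cols, ihc_cols, floor_shlag)
                )
            except (ValueError, KeyError) as err:
                errors.append(f"line {lineno} (subject {sid!r}): {err}")
    if errors and not skip_bad:
        raise BadRowsError(errors)
    return records, errors


def _parse_row(
    row: dict,
    defs: Sequence[UTRHaplotypeDefinition],
    clinical_cols: list[str],
    ihc_cols: list[str],
    floor_shlag: bool,
) -> SubjectRecord:
    chromosomes = []
    for i in (1, 2):
        motif_text = (row.get(f"motif_{i}") or "").strip()
        sites = parse_motif(motif_text)
        label_text = (row.get(f"utr_label_{i}") or "").strip()
        if label_text:
            labels: tuple[str, ...] = tuple(label_text.split("|"))
        else:
            labels = assign_utr_haplotype(sites, defs).labels
        block_text = (row.get(f"utr_allele_block_{i}") or "").strip()
        alleles = _parse_allele_block(block_text) if block_text else {}
        chromosomes.append(
            Chromosome(utr_labels=labels, alleles=alleles, motif=sites.compact())
        )

    shlag_text = (row.get("sHLA_G") or "").strip()
    shlag = float(shlag_text) if shlag_text else None
    if shlag is not None and floor_shlag:
        shlag = max(shlag, 0.6)
    inflammation = (row.get("inflammation") or "").strip() or None
    biopsied = (row.get("biopsied") or "").strip() in ("1", "True", "true", "yes")
    ihc = {
        col[len(_IHC_PREFIX):]: histology.parse_percent(row[col])
        for col in ihc_cols
        if (row.get(col) or "").strip()
    }
    clinical = {
        col: _parse_clinical(row[col].strip())
        for col in clinical_cols
        if (row.get(col) or "").strip()
    }
    return SubjectRecord(
        subject_id=row["subject_id"].strip(),
        cohort=row["cohort"].strip(),
        chromosomes=tuple(chromosomes),
        shlag=shlag,
        inflammation=inflammation,
        biopsied=biopsied,
        ihc=ihc,
        clinical=clinical,
    )


def _fmt(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "True" if value else "False"
    if isinstance(value, float):
        return format(value, ".10g")
    return str(value)


def write_subjects(records: Iterable[SubjectRecord], path) -> None:
    """Write subjects in the canonical TSV dialect (stable column order)."""
    records = list(records)
    clinical_cols = sorted({c for r in records for c in r.clinical})
    ihc_cols = sorted({c for r in records for c in r.ihc})
    columns = list(_STRUCTURAL_COLUMNS) + [_IHC_PREFIX + c for c in ihc_cols] + clinical_cols
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for r in records:
            if len(r.chromosomes) != 2:
                raise ValueError(f"subject {r.subject_id!r} does not have 2 chromosomes")
            row = {
                "subject_id": r.subject_id,
                "cohort": r.cohort,
                "motif_1": r.chromosomes[0].motif or "",
                "motif_2": r.chromosomes[1].motif or "",
                "utr_label_1": "|".join(r.chromosomes[0].utr_labels),
                "utr_label_2": "|".join(r.chromosomes[1].utr_labels),
                "utr_allele_block_1": _format_allele_block(dict(r.chromosomes[0].alleles)),
                "utr_allele_block_2": _format_allele_block(dict(r.chromosomes[1].alleles)),
                "sHLA_G": _fmt(r.shlag),
                "inflammation": r.inflammation or "",
                "biopsied": "1" if r.biopsied else "",
            }
            for c in ihc_cols:
                row[_IHC_PREFIX + c] = _fmt(r.ihc.get(c))
            for c in clinical_cols:
                row[c] = _fmt(r.clinical.get(c))
            writer.writerow([row[c] for c in columns])
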