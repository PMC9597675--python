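"""Shared subject-level containers.

A subject contributes two chromosomes; each chromosome carries a resolved
HLA-G 3'UTR haplotype call plus (optionally) phased classical-HLA alleles,
which is what the linkage-disequilibrium analysis consumes. Plasma soluble
HLA-G, inflammation grade, immunohistochemistry readings and arbitrary
clinical variables hang off the subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

#: Inflammation grades used throughout (liver biopsy, hepatitis activity).
INFLAMMATION_GRADES = ("mild", "moderate", "severe")

#: ELISA detection limit for soluble HLA-G, U/mL.
SHLAG_DETECTION_LIMIT = 0.6


@dataclass(frozen=True)
class Chromosome:
    """One phased chromosome: a UTR haplotype call plus classical alleles.

    ``utr_labels`` holds the candidate UTR haplotype names: one entry for a
    clean assignment, several for an ambiguous motif (two definitions share
    a printed motif), none when the motif matches no definition.
    ``alleles`` maps locus name ("A", "B", "C", "DRB1", "HLA-G", ...) to an
    opaque allele string such as "03:01"; allele names are never parsed.
    """

    utr_labels: tuple[str, ...] = ()
    alleles: Mapping[str, str] = field(default_factory=dict)
    motif: str | None = None

    @property
    def utr_label(self) -> str | None:
        """Single resolved label, a composite "X|Y" when ambiguous, else None."""
        if not self.utr_labels:
            return None
        if len(self.utr_labels) == 1:
            return self.utr_labels[0]
        return "|".join(sorted(self.utr_labels))

    def carries(self, allele_set: Mapping[str, str]) -> bool:
        """True if this chromosome carries every locus->allele pair given."""
        return all(self.alleles.get(locus) == allele for locus, allele in allele_set.items())


@dataclass
class SubjectRecord:
    """One study subject (patient or control) with two resolved chromosomes."""

    subject_id: str
    cohort: str
    chromosomes: tuple[Chromosome, ...]
    shlag: float | None = None
    inflammation: str | None = None
    biopsied: bool = False
    #: cell_type -> percent positive (float) or the "<25" borderline sentinel.
    ihc: dict[str, object] = field(default_factory=dict)
    clinical: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.shlag is not None and self.shlag < 0:
            raise ValueError(
                f"subject {self.subject_id!r}: sHLA-G must be non-negative, got {self.shlag}"
            )
        if self.inflammation is not None and self.inflammation not in INFLAMMATION_GRADES:
            raise ValueError(
                f"subject {self.subject_id!r}: unknown inflammation grade {self.inflammation!r}"
            )

    @property
    def utr1_carrier(self) -> bool:
        return any(ch.utr_label == "UTR-1" for ch in self.chromosomes)

    def carrier_of(self, label: str) -> bool:
        return any(ch.utr_label == label for ch in self.chromosomes)
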