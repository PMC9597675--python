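"""HLA-G 3'UTR haplotype model.

The 3' untranslated region of HLA-G carries eight polymorphic sites — a
14-bp insertion/deletion plus seven biallelic SNPs (3003C/T, 3010C/G,
3027A/C, 3035C/T, 3142C/G, 3187A/G, 3196C/G) — whose combinations define
the named UTR haplotypes (UTR-1, UTR-2, ...). Chromosomes are classified by
exact motif lookup against a definition table; the built-in definitions are
the eleven haplotypes observed in the Sardinian case-control panel this
package reproduces, including one motif (DelTGCCCAC) printed under two
names (UTR-18 and UTR-6), which therefore assigns ambiguously.

Motifs are modeled as categorical site states; genomic coordinates
(+2945..+3259 relative to the start codon) are metadata the analysis never
uses.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .records import Chromosome, SubjectRecord

#: Site name -> the two admissible states, in 3'UTR order.
SITES: tuple[tuple[str, tuple[str, str]], ...] = (
    ("14bp", ("Ins", "Del")),
    ("3003", ("C", "T")),
    ("3010", ("C", "G")),
    ("3027", ("A", "C")),
    ("3035", ("C", "T")),
    ("3142", ("C", "G")),
    ("3187", ("A", "G")),
    ("3196", ("C", "G")),
)

SITE_NAMES = tuple(name for name, _ in SITES)


@dataclass(frozen=True)
class UTRSiteVector:
    """States at the eight 3'UTR polymorphic sites, e.g. (Del,T,G,C,C,C,G,C)."""

    indel14bp: str
    s3003: str
    s3010: str
    s3027: str
    s3035: str
    s3142: str
    s3187: str
    s3196: str

    def __post_init__(self) -> None:
        for (site, states), value in zip(SITES, self.states):
            if value not in states:
                raise ValueError(
                    f"site {site}: state {value!r} not one of {'/'.join(states)}"
                )

    @property
    def states(self) -> tuple[str, ...]:
        return (
            self.indel14bp,
            self.s3003,
            self.s3010,
            self.s3027,
            self.s3035,
            self.s3142,
            self.s3187,
            self.s3196,
        )

    def compact(self) -> str:
        """Render as the compact motif string, e.g. "DelTGCCCGC"."""
        return self.indel14bp + "".join(self.states[1:])

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.compact()


def parse_motif(text: str) -> UTRSiteVector:
    """Parse a compact motif string ("DelTGCCCGC") into a site vector.

    The first three letters are the 14-bp indel token (Ins/Del), followed by
    one nucleotide per SNP site. Raises ValueError naming the offending site
    on malformed input.
    """
    if not isinstance(text, str) or len(text) != 10:
        raise ValueError(
            f"motif {text!r}: expected 3-letter Ins/Del token plus 7 nucleotides (length 10)"
        )
    indel = text[:3]
    if indel not in SITES[0][1]:
        raise ValueError(f"site 14bp: token {indel!r} not one of Ins/Del")
    states = [indel]
    for (site, allowed), letter in zip(SITES[1:], text[3:]):
        if letter not in allowed:
            raise ValueError(f"site {site}: letter {letter!r} not one of {'/'.join(allowed)}")
        states.append(letter)
    return UTRSiteVector(*states)


@dataclass(frozen=True)
class UTRHaplotypeDefinition:
    """A named UTR haplotype: label plus its eight-site motif."""

    label: str
    motif: UTRSiteVector


@dataclass(frozen=True)
class HaplotypeCall:
    """Outcome of motif lookup: assigned, ambiguous (>=2 labels) or unassigned."""

    labels: tuple[str, ...]

    @property
    def is_unassigned(self) -> bool:
        return len(self.labels) == 0

    @property
    def is_ambiguous(self) -> bool:
        return len(self.labels) >= 2

    @property
    def label(self) -> str | None:
        """Resolved label, composite "X|Y" for ambiguous calls, None if unassigned."""
        if not self.labels:
            return None
        if len(self.labels) == 1:
            return self.labels[0]
        return "|".join(sorted(self.labels))


# Table of (label, motif) pairs as observed in the study panel. Note the
# duplicated motif under UTR-18 and UTR-6: retained as printed, surfaced as
# an ambiguous call at assignment time, never silently resolved.
_DEFAULT_ROWS = (
    ("UTR-1", "DelTGCCCGC"),
    ("UTR-2", "InsTCCCGAG"),
    ("UTR-5", "InsTCCTGAC"),
    ("UTR-3", "DelTCCCGAC"),
    ("UTR-7", "InsTCATGAC"),
    ("UTR-4", "DelCGCCCAC"),
    ("UTR-18", "DelTGCCCAC"),
    ("UTR-10", "DelTCCCGAG"),
    ("UTR-6", "DelTGCCCAC"),
    ("UTR-8", "InsTGCCGAG"),
    ("UTR-13", "DelTCCTGAC"),
)


def default_definitions() -> list[UTRHaplotypeDefinition]:
    """The built-in UTR haplotype definition set (11 entries)."""
    return [UTRHaplotypeDefinition(label, parse_motif(motif)) for label, motif in _DEFAULT_ROWS]


def validate_definitions(defs: Sequence[UTRHaplotypeDefinition]) -> list[str]:
    """Check label uniqueness; return the motifs shared by several labels.

    Duplicate motifs are permitted (they exist in the built-in set) but are
    reported so callers know which assignments will be ambiguous.
    """
    labels = [d.label for d in defs]
    dupes = [label for label, k in Counter(labels).items() if k > 1]
    if dupes:
        raise ValueError(f"duplicate haplotype labels in definition set: {dupes}")
    motif_counts = Counter(d.motif.compact() for d in defs)
    return [m for m, k in motif_counts.items() if k > 1]


def assign_utr_haplotype(
    sites: UTRSiteVector, defs: Sequence[UTRHaplotypeDefinition] | None = None
) -> HaplotypeCall:
    """Exact-match lookup of a site vector against a definition set.

    A unique match yields that label; several matching labels yield an
    ambiguous call carrying all of them; no match yields an unassigned call
    (a value, not an error).
    """
    if defs is None:
        defs = default_definitions()
    if not defs:
        raise ValueError("definition set is empty")
    target = sites.compact()
    matches = tuple(d.label for d in defs if d.motif.compact() == target)
    return HaplotypeCall(matches)


@dataclass
class CohortHaplotypeTable:
    """Per-cohort haplotype-key counts over 2N chromosomes."""

    cohort_name: str
    two_n: int
    counts: dict[object, int]

    def __post_init__(self) -> None:
        if self.two_n <= 0:
            raise ValueError(f"cohort {self.cohort_name!r}: 2N must be positive, got {self.two_n}")
        bad = {k: v for k, v in self.counts.items() if v < 0}
        if bad:
            raise ValueError(f"negative counts: {bad}")
        if sum(self.counts.values()) > self.two_n:
            raise ValueError(
                f"cohort {self.cohort_name!r}: counts sum to more than 2N={self.two_n}"
            )

    @property
    def unassigned(self) -> int:
        return self.two_n - sum(self.counts.values())

    def frequency(self, key: object) -> float:
        return self.counts.get(key, 0) / self.two_n


# Haplotype-key selectors for tabulate(). Each maps a chromosome to a
# hashable key, or None for "does not contribute a key" (counted as
# unassigned but still part of 2N).

def key_utr(ch: Chromosome) -> str | None:
    """UTR haplotype label (frequency tables over UTR haplotypes)."""
    return ch.utr_label


def key_allele(locus: str) -> Callable[[Chromosome], str | None]:
    """Allele at one classical locus (allele frequency tables)."""

    def _key(ch: Chromosome) -> str | None:
        return ch.alleles.get(locus)

    return _key


def key_extended(locus: str = "HLA-G") -> Callable[[Chromosome], tuple | None]:
    """(allele, UTR label) pair — the extended-haplotype tables."""

    def _key(ch: Chromosome) -> tuple | None:
        allele = ch.alleles.get(locus)
        label = ch.utr_label
        if allele is None or label is None:
            return None
        return (allele, label)

    return _key


def tabulate(
    cohort: Iterable[SubjectRecord],
    key: Callable[[Chromosome], object] = key_utr,
    cohort_name: str = "",
) -> CohortHaplotypeTable:
    """Count haplotype keys over a cohort's chromosomes.

    Every subject must contribute exactly two resolved chromosomes; 2N is
    twice the subject count and chromosomes whose key is None are counted
    in 2N but not in any key (conservation: sum(counts) + unassigned = 2N).
    """
    counts: Counter = Counter()
    n_subjects = 0
    for subject in cohort:
        if len(subject.chromosomes) != 2:
            raise ValueError(
                f"subject {subject.subject_id!r} has {len(subject.chromosomes)} resolved "
                "haplotypes; exactly 2 required"
            )
        n_subjects += 1
        for ch in subject.chromosomes:
            k = key(ch)
            if k is not None:
                counts[k] += 1
    if n_subjects == 0:
        raise ValueError("empty cohort: cannot tabulate over 0 chromosomes")
    return CohortHaplotypeTable(cohort_name=cohort_name, two_n=2 * n_subjects, counts=dict(counts))
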