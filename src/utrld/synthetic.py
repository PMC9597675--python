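"""Seeded two-cohort generator with the statistical structure the analysis assumes.

Emulates the study design this package reproduces: a patient cohort and a
population control cohort, each subject contributing two phased chromosomes
(a UTR haplotype plus classical-HLA alleles), with

* per-cohort UTR haplotype frequencies (defaults: the published
  case-control counts over 2N = 410 / 420 chromosomes),
* one linked classical marker held at a per-cohort target D' (defaults:
  UTR-1 x DRB1*03:01 at D' 0.92 in patients, 0.50 in controls, with the
  published marginal frequencies),
* an extended ancestral block (A*30:02 ~ B*18:01 ~ C*05:01) riding on a
  configurable fraction of the linked-marker chromosomes,
* log-normal soluble HLA-G stratified by a latent inflammation grade and
  shifted multiplicatively for UTR-1 carriers,
* a biopsied subset with semiquantitative IHC readings and a few clinical
  chemistry variables.

Chromosomes pair by random union within cohort (Hardy–Weinberg); there is
no family structure, no genotyping error, and no coalescent realism.
Regenerating with the same config and seed is bit-identical.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .haplotypes import default_definitions
from .records import Chromosome, SubjectRecord

# Published per-cohort UTR haplotype counts (controls over 2N=420,
# patients over 2N=410) used as default generator frequencies.
_CONTROL_COUNTS = {
    "UTR-1": 144, "UTR-2": 107, "UTR-5": 67, "UTR-3": 34, "UTR-7": 28,
    "UTR-4": 26, "UTR-18": 7, "UTR-10": 5, "UTR-6": 2,
}
_PATIENT_COUNTS = {
    "UTR-1": 165, "UTR-2": 105, "UTR-5": 35, "UTR-3": 30, "UTR-7": 25,
    "UTR-4": 35, "UTR-18": 0, "UTR-10": 5, "UTR-6": 10,
}

OTHER_LABEL = "other"
#: valid 8-site motif matching no built-in definition; carried by catch-all
#: chromosomes so subject tables always round-trip through the motif parser.
UNASSIGNED_MOTIF = "InsTGCCCGC"

_BACKGROUND_ALLELES = {
    "A": ["02:01", "24:02", "01:01", "11:01"],
    "B": ["35:01", "51:01", "44:03", "15:01"],
    "C": ["04:01", "07:01", "12:03", "16:01"],
    "DRB1": ["04:05", "07:01", "11:04", "16:01"],
}


def _default_utr_freqs() -> dict[str, dict[str, float]]:
    return {
        "control": {k: v / 420 for k, v in _CONTROL_COUNTS.items()},
        "patient": {k: v / 410 for k, v in _PATIENT_COUNTS.items()},
    }


@dataclass
class SimulationConfig:
    """Generator configuration; defaults are the published study conditions."""

    n_patients: int = 205
    n_controls: int = 210
    #: cohort -> UTR label -> haplotype frequency (sums <= 1; remainder
    #: becomes the catch-all ``other`` label).
    utr_freqs: dict[str, dict[str, float]] = field(default_factory=_default_utr_freqs)
    #: linked classical marker: UTR label x locus alleles at a target D'.
    marker_a: str = "UTR-1"
    marker_b_alleles: dict[str, str] = field(default_factory=lambda: {"DRB1": "03:01"})
    d_prime: dict[str, float] = field(
        default_factory=lambda: {"control": 0.50, "patient": 0.92}
    )
    p_b: dict[str, float] = field(
        default_factory=lambda: {"control": 91 / 420, "patient": 159 / 410}
    )
    #: extended ancestral block carried by a fraction of marker-B chromosomes
    #: (published conditional fractions: complete haplotype / DRB1*03:01).
    block_alleles: dict[str, str] = field(
        default_factory=lambda: {"A": "30:02", "B": "18:01", "C": "05:01"}
    )
    block_prob: dict[str, float] = field(
        default_factory=lambda: {"control": 43 / 91, "patient": 89 / 159}
    )
    background_alleles: dict[str, list[str]] = field(
        default_factory=lambda: copy.deepcopy(_BACKGROUND_ALLELES)
    )
    #: soluble HLA-G: log-normal per stratum; medians in U/mL.
    shlag_medians: dict[str, float] = field(
        default_factory=lambda: {
            "control": 21.3,
            "patient_mild_moderate": 33.5,
            "patient_severe": 8.8,
            "patient_unbiopsied": 13.9,
        }
    )
    shlag_sigma: float = 1.1
    utr1_shift: float = 1.35  # multiplicative sHLA-G shift for UTR-1 carriers
    #: inflammation grade distribution among the biopsied patients (biopsy
    #: was clinically indicated in the emulated study, so the biopsied
    #: subset is not a random draw of the cohort; unbiopsied patients carry
    #: no grade and follow the cohort-level sHLA-G median and
    #: mild/moderate-grade biochemistry).
    inflammation_probs: dict[str, float] = field(
        default_factory=lambda: {"mild": 12 / 52, "moderate": 12 / 52, "severe": 28 / 52}
    )
    n_biopsied: int = 52
    #: IHC plasma-cell positivity probability by severity stratum.
    ihc_positive_prob: dict[str, float] = field(
        default_factory=lambda: {"severe": 1.0, "mild_moderate": 8 / 24}
    )
    #: clinical chemistry: variable -> (median mild/moderate, median severe, log-sd)
    clinical_models: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "ALT": (50.0, 120.0, 0.9),
            "AST": (45.0, 100.0, 0.8),
            "ALP": (120.0, 200.0, 0.5),
            "gamma_globulin": (1.6, 2.0, 0.3),
        }
    )

    def validate(self) -> "SimulationConfig":
        for cohort, freqs in self.utr_freqs.items():
            total = sum(freqs.values())
            if total > 1.0 + 1e-9:
                raise ValueError(f"{cohort} UTR frequencies sum to {total} > 1")
            if any(f < 0 for f in freqs.values()):
                raise ValueError(f"{cohort} has a negative UTR frequency")
        for cohort in ("control", "patient"):
            if not -1.0 <= self.d_prime[cohort] <= 1.0:
                raise ValueError(f"{cohort} target D' outside [-1, 1]")
        if self.shlag_sigma <= 0:
            raise ValueError("shlag_sigma must be positive")
        total = sum(self.inflammation_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"inflammation grade probabilities sum to {total}, not 1")
        return self


def two_locus_freqs_from_dprime(
    p_a: float, p_b: float, d_prime_target: float
) -> tuple[float, float, float, float]:
    """Joint haplotype frequencies (f_AB, f_Ab, f_aB, f_ab) at a target D'.

    Inverts the Lewontin normalization: D = D'_target * D_max with D_max
    the margin-constrained maximum for the sign of D, so the four joint
    frequencies are non-negative by construction.
    """
    if not -1.0 <= d_prime_target <= 1.0:
        raise ValueError(f"target D' {d_prime_target} outside [-1, 1]")
    if not (0.0 < p_a < 1.0 and 0.0 < p_b < 1.0):
        if d_prime_target != 0.0:
            raise ValueError(
                f"margins ({p_a}, {p_b}) are fixed; no D' other than 0 is attainable"
            )
        d = 0.0
    elif d_prime_target >= 0:
        d = d_prime_target * min(p_a * (1.0 - p_b), (1.0 - p_a) * p_b)
    else:
        d = d_prime_target * min(p_a * p_b, (1.0 - p_a) * (1.0 - p_b))
    f_ab_joint = p_a * p_b + d
    return (
        f_ab_joint,
        p_a - f_ab_joint,
        p_b - f_ab_joint,
        1.0 - p_a - p_b + f_ab_joint,
    )


@dataclass
class SyntheticDataset:
    subjects: list[SubjectRecord]
    config: SimulationConfig
    seed: int

    @property
    def provenance(self) -> dict:
        return {"seed": self.seed, "config": asdict(self.config)}


_IHC_SEVERE_PERCENTS = ([25.0] * 4 + [50.0] * 8 + [75.0] * 4 + [100.0] * 12)
_IHC_MILD_PERCENTS = ["<25"] * 4 + [25.0] * 4


def _label_motifs() -> dict[str, str]:
    return {d.label: d.motif.compact() for d in default_definitions()}


def _draw_chromosome(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    cohort: str,
    labels: Sequence[str],
    probs: np.ndarray,
    cond_b_given_a: float,
    cond_b_given_not_a: float,
    motifs: dict[str, str],
) -> Chromosome:
    label = labels[rng.choice(len(labels), p=probs)]
    is_a = label == cfg.marker_a
    p_carry = cond_b_given_a if is_a else cond_b_given_not_a
    carries_b = rng.random() < p_carry
    alleles: dict[str, str] = {}
    if carries_b:
        alleles.update(cfg.marker_b_alleles)
        if rng.random() < cfg.block_prob[cohort]:
            alleles.update(cfg.block_alleles)
    for locus, pool in cfg.background_alleles.items():
        if locus not in alleles:
            alleles[locus] = pool[rng.choice(len(pool))]
    return Chromosome(
        utr_labels=(label,) if label != OTHER_LABEL else (),
        alleles=alleles,
        motif=motifs.get(label, UNASSIGNED_MOTIF),
    )


def simulate(config: SimulationConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Draw a full two-cohort synthetic dataset; deterministic under seed."""
    cfg = (config or SimulationConfig()).validate()
    rng = np.random.default_rng(seed)
    motifs = _label_motifs()
    grades = list(cfg.inflammation_probs)
    grade_probs = np.array([cfg.inflammation_probs[g] for g in grades])

    subjects: list[SubjectRecord] = []
    for cohort, n_subjects, prefix in (
        ("control", cfg.n_controls, "C"),
        ("patient", cfg.n_patients, "P"),
    ):
        freqs = cfg.utr_freqs[cohort]
        labels = list(freqs) + [OTHER_LABEL]
        probs = np.array(list(freqs.values()) + [max(0.0, 1.0 - sum(freqs.values()))])
        probs = probs / probs.sum()
        p_a = freqs.get(cfg.marker_a, 0.0)
        p_b = cfg.p_b[cohort]
        if not (0.0 < p_a < 1.0):
            raise ValueError(
                f"{cohort}: marker pair ({cfg.marker_a}, {cfg.marker_b_alleles}) "
                "infeasible: marker A frequency must lie strictly in (0, 1)"
            )
        f_ab, _, f_a_not, _ = two_locus_freqs_from_dprime(p_a, p_b, cfg.d_prime[cohort])
        cond_b_given_a = f_ab / p_a
        cond_b_given_not_a = f_a_not / (1.0 - p_a)

        # inflammation grades exist only for the biopsied patient subset
        if cohort == "patient":
            biopsied_idx = set(
                rng.choice(n_subjects, size=min(cfg.n_biopsied, n_subjects), replace=False)
            )
            drawn = iter(
                grades[i]
                for i in rng.choice(len(grades), size=len(biopsied_idx), p=grade_probs)
            )
            latent = [next(drawn) if i in biopsied_idx else None for i in range(n_subjects)]
        else:
            latent = [None] * n_subjects
            biopsied_idx = set()

        for i in range(n_subjects):
            chromosomes = tuple(
                _draw_chromosome(
                    rng, cfg, cohort, labels, probs,
                    cond_b_given_a, cond_b_given_not_a, motifs,
                )
                for _ in range(2)
            )
            grade = latent[i]
            if cohort == "control":
                stratum = "control"
            elif grade is None:
                stratum = "patient_unbiopsied"
            elif grade == "severe":
                stratum = "patient_severe"
            else:
                stratum = "patient_mild_moderate"
            carrier = any(ch.utr_label == cfg.marker_a for ch in chromosomes)
            carrier_frac = 1.0 - (1.0 - p_a) ** 2
            mu = np.log(cfg.shlag_medians[stratum]) - carrier_frac * np.log(cfg.utr1_shift)
            if carrier:
                mu += np.log(cfg.utr1_shift)
            shlag = float(np.exp(rng.normal(mu, cfg.shlag_sigma)))

            biopsied = i in biopsied_idx
            ihc: dict[str, object] = {}
            clinical: dict[str, object] = {}
            if cohort == "patient":
                severe = grade == "severe"
                for var, (med_mm, med_sev, sd) in cfg.clinical_models.items():
                    med = med_sev if severe else med_mm
                    clinical[var] = float(np.exp(rng.normal(np.log(med), sd)))
                if biopsied:
                    p_pos = cfg.ihc_positive_prob["severe" if severe else "mild_moderate"]
                    if rng.random() < p_pos:
                        pool = _IHC_SEVERE_PERCENTS if severe else _IHC_MILD_PERCENTS
                        ihc["plasma_cells"] = pool[rng.choice(len(pool))]
                    else:
                        ihc["plasma_cells"] = 0.0
                    ihc["hepatocytes_endothelial"] = 0.0

            subjects.append(
                SubjectRecord(
                    subject_id=f"{prefix}{i + 1:04d}",
                    cohort=cohort,
                    chromosomes=chromosomes,
                    shlag=shlag,
                    inflammation=grade if biopsied else None,
                    biopsied=biopsied,
                    ihc=ihc,
                    clinical=clinical,
                )
            )
    return SyntheticDataset(subjects=subjects, config=cfg, seed=seed)
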