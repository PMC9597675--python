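"""End-to-end orchestration: run every analysis stage on one subject file.

Produces the study's table shapes as TSVs — UTR-haplotype association
(frequency table), extended-haplotype association when HLA-G alleles are
present, linkage disequilibrium, clinical group comparison, IHC scoring —
plus a machine-readable JSON summary embedding the tool version, a config
hash and the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__, association, histology, io, ld, soluble
from .haplotypes import key_extended, key_utr, tabulate
from .records import SubjectRecord

log = logging.getLogger("utrld")


def format_p(p: float | None) -> str:
    """P values as the tables print them: 3 dp at or above 0.001, scientific
    with 2 significant figures below."""
    if p is None:
        return ""
    if p >= 0.001:
        return f"{p:.3f}"
    exponent = math.floor(math.log10(p))
    mantissa = p / 10**exponent
    return f"{mantissa:.1f}e{exponent:+03d}"


@dataclass
class RunConfig:
    subjects: str | Path
    out_dir: str | Path = "utrld-out"
    cohort1: str = "control"
    cohort2: str = "patient"
    alpha: float = 0.05
    bonferroni_mode: str | int = "shared_nonzero"
    p_method: str = "as_published"
    or_method: str = "woolf"
    pc_policy: str = "printed"
    marker_a: str = "UTR-1"
    loci: Sequence[str] = ("A", "B", "C", "DRB1")
    marker_b_alleles: dict[str, str] = field(
        default_factory=lambda: {"A": "30:02", "B": "18:01", "C": "05:01", "DRB1": "03:01"}
    )
    contrast: str = "as-published"
    seed: int = 0
    skip_bad: bool = False
    floor_shlag: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")

    def config_hash(self) -> str:
        # hash the analysis-relevant parameters; the output location is not
        # part of the analysis identity
        payload = asdict(self)
        payload["subjects"] = str(payload["subjects"])
        del payload["out_dir"]
        payload["loci"] = list(payload["loci"])
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def association_frame(rows: list[association.AssociationRow]) -> pd.DataFrame:
    """Association rows as a frequency-table-shaped DataFrame."""
    out = []
    for r in rows:
        ci = (
            f"{r.or_est:.3f} ({r.ci_low:.3f} – {r.ci_high:.3f})"
            if r.or_est is not None
            else ""
        )
        out.append(
            {
                "key": r.key if isinstance(r.key, str) else " / ".join(map(str, r.key)),
                "n1": r.n1,
                "f1": round(r.f1, 4),
                "n2": r.n2,
                "f2": round(r.f2, 4),
                "P": format_p(r.p),
                "OR (95% CI)": ci,
                "Pc": format_p(r.pc) if r.pc is not None else "",
                "note": r.note or "",
            }
        )
    return pd.DataFrame(out)


def ld_frame(reports: list[ld.LDPairReport]) -> pd.DataFrame:
    """LD reports as a DataFrame mirroring the published LD table layout."""
    out = []
    for rep in reports:
        row = {"pair": ", ".join(f"{locus}*{allele}" for locus, allele in rep.pair)}
        for tag, obs, res in (("1", rep.obs1, rep.res1), ("2", rep.obs2, rep.res2)):
            row[f"n_obs_{tag}"] = obs.n_ab
            row[f"f_obs_{tag}_pct"] = round(100 * obs.f_ab_obs, 2)
            row[f"n_exp_{tag}"] = res.n_exp
            row[f"f_exp_{tag}_pct"] = round(100 * res.f_ab_exp, 2)
            row[f"D_{tag}_pct"] = round(100 * res.d, 2)
            row[f"Dprime_{tag}"] = (
                round(res.d_prime, 2) if res.d_prime is not None else None
            )
            row[f"chi2_{tag}"] = round(res.chi2, 2) if res.chi2 is not None else None
        row["P"] = format_p(rep.contrast.p) if rep.contrast is not None else ""
        row["note"] = rep.note or ""
        out.append(row)
    return pd.DataFrame(out)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"stage {name!r} failed: {err}") from err

        return wrapped

    return deco


def run_all(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns output paths."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    records, row_errors = _stage("read_subjects")(io.read_subjects)(
        config.subjects, skip_bad=config.skip_bad, floor_shlag=config.floor_shlag
    )
    cohort1 = [r for r in records if r.cohort == config.cohort1]
    cohort2 = [r for r in records if r.cohort == config.cohort2]
    if not cohort1 or not cohort2:
        raise RuntimeError(
            f"stage 'split_cohorts' failed: need subjects in both cohorts "
            f"{config.cohort1!r} and {config.cohort2!r}"
        )

    @_stage("association")
    def _assoc() -> pd.DataFrame:
        t1 = tabulate(cohort1, key_utr, config.cohort1)
        t2 = tabulate(cohort2, key_utr, config.cohort2)
        rows = association.associate(
            t1, t2,
            m=config.bonferroni_mode,
            alpha=config.alpha,
            p_method=config.p_method,
            or_method=config.or_method,
            pc_policy=config.pc_policy,
        )
        return association_frame(rows)

    df = _assoc()
    outputs["association"] = out_dir / "association_utr.tsv"
    df.to_csv(outputs["association"], sep="\t", index=False)

    has_g_alleles = any(
        "HLA-G" in ch.alleles for r in records for ch in r.chromosomes
    )
    if has_g_alleles:
        @_stage("association_extended")
        def _assoc_ext() -> pd.DataFrame:
            t1 = tabulate(cohort1, key_extended(), config.cohort1)
            t2 = tabulate(cohort2, key_extended(), config.cohort2)
            rows = association.associate(
                t1, t2, m="all_rows", alpha=config.alpha,
                p_method=config.p_method, or_method=config.or_method,
                pc_policy=config.pc_policy,
            )
            return association_frame(rows)

        outputs["association_extended"] = out_dir / "association_extended.tsv"
        _assoc_ext().to_csv(outputs["association_extended"], sep="\t", index=False)

    @_stage("ld")
    def _ld() -> pd.DataFrame:
        reports = ld.ld_table(
            cohort1, cohort2,
            marker_a=config.marker_a,
            marker_b_alleles=dict(config.marker_b_alleles),
            loci=tuple(config.loci),
            contrast=config.contrast,
            seed=config.seed,
        )
        return ld_frame(reports)

    outputs["ld"] = out_dir / "ld.tsv"
    _ld().to_csv(outputs["ld"], sep="\t", index=False)

    @_stage("group_compare")
    def _groups() -> pd.DataFrame:
        frames = []
        df = soluble.group_compare(records, "patient_vs_control", alpha=config.alpha)
        df.insert(0, "grouping", "patient_vs_control")
        frames.append(df)
        if any(r.inflammation == "severe" for r in records):
            df = soluble.group_compare(records, "severe_vs_rest", alpha=config.alpha)
            df.insert(0, "grouping", "severe_vs_rest")
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    outputs["group_compare"] = out_dir / "group_compare.tsv"
    _groups().to_csv(outputs["group_compare"], sep="\t", index=False)

    ihc_summary: dict = {}

    @_stage("ihc")
    def _ihc() -> pd.DataFrame | None:
        rows = []
        for r in records:
            for cell_type, percent in sorted(r.ihc.items()):
                rows.append(
                    {
                        "biopsy_id": r.subject_id,
                        "inflammation": r.inflammation or "",
                        "cell_type": cell_type,
                        "percent": percent,
                    }
                )
        if not rows:
            return None
        df = histology.score_table(pd.DataFrame(rows))
        if (df["cell_type"] == "plasma_cells").any():
            ihc_summary["plasma_cell_positivity_rate"] = histology.plasma_cell_positivity_rate(df)
        return df

    ihc_df = _ihc()
    if ihc_df is not None:
        outputs["ihc"] = out_dir / "ihc.tsv"
        ihc_df.to_csv(outputs["ihc"], sep="\t", index=False)

    summary = {
        "tool": "utrld",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": {config.cohort1: len(cohort1), config.cohort2: len(cohort2)},
        "skipped_rows": row_errors,
        "outputs": {k: str(v.name) for k, v in outputs.items()},
        **ihc_summary,
    }
    outputs["summary"] = out_dir / "summary.json"
    outputs["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return outputs
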