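"""Semiquantitative immunohistochemistry scoring for HLA-G positivity.

Pathologists report, per biopsy and cell type, the percentage of cells
staining positive for HLA-G (staining intensity is ignored by design).
Percentages map to an ordinal 0-4 score with a symbol:

    0%        -> 0  (-)
    "<25"     -> 1  (+/-)  borderline: positive but below the first band
    1-25%     -> 1  (+)
    26-50%    -> 2  (++)
    51-75%    -> 3  (+++)
    76-100%   -> 4  (++++)

The "<25" readings are kept as a distinct sentinel rather than coerced to a
number. The mapping follows the symbol usage attested throughout the
packaged biopsy table (the procedural description of the scheme in the
source study is internally garbled; see docs/methods.md).

Inter-rater agreement is simple percent agreement: per variable, the mean
over rater pairs of the fraction of biopsies scored identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

BORDERLINE = "<25"

CELL_TYPES = (
    "plasma_cells",
    "hepatocytes_endothelial",
    "kupffer",
    "histiocytes_macrophages",
)

_SYMBOLS = {0: "-", 1: "+", 2: "++", 3: "+++", 4: "++++"}


@dataclass(frozen=True)
class IHCScore:
    numeric: int
    symbol: str
    borderline: bool = False


@dataclass(frozen=True)
class IHCObservation:
    """One biopsy x cell-type reading."""

    biopsy_id: str
    cell_type: str
    percent: object  # float in [0, 100] or the "<25" sentinel
    localization: frozenset[str] = frozenset()  # subset of {"M", "C"}
    inflammation: str | None = None

    def __post_init__(self) -> None:
        score_percent(self.percent)  # validates
        is_negative = self.percent == 0
        if is_negative and self.localization:
            raise ValueError(
                f"biopsy {self.biopsy_id!r}: negative staining cannot have a localization"
            )


def score_percent(percent: object) -> IHCScore:
    """Map a percent-positive reading (or the "<25" sentinel) to its score."""
    if isinstance(percent, str):
        if percent.strip() == BORDERLINE:
            return IHCScore(1, "+/-", borderline=True)
        raise ValueError(f"unrecognized percent value {percent!r}")
    value = float(percent)
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"percent {value} outside [0, 100]")
    if value == 0.0:
        numeric = 0
    elif value <= 25.0:
        numeric = 1
    elif value <= 50.0:
        numeric = 2
    elif value <= 75.0:
        numeric = 3
    else:
        numeric = 4
    return IHCScore(numeric, _SYMBOLS[numeric])


def parse_percent(text: str) -> object:
    """Parse a percent cell from the observation TSV ("<25" stays a sentinel)."""
    text = text.strip()
    if text == BORDERLINE:
        return BORDERLINE
    return float(text)


def load_packaged_biopsies() -> pd.DataFrame:
    """The packaged 52-biopsy transcription (long format, one row per
    biopsy x cell type) with columns biopsy_id, aih_type, inflammation,
    cell_type, percent, symbol, localization."""
    with resources.files("utrld.data").joinpath("liver_biopsy_ihc.tsv").open("r") as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    df["percent"] = df["percent"].map(parse_percent)
    return df


def read_observations(path) -> pd.DataFrame:
    """Read an observation TSV in the same dialect as the packaged table."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"biopsy_id", "cell_type", "percent"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    df["percent"] = df["percent"].map(parse_percent)
    return df


def score_table(df: pd.DataFrame) -> pd.DataFrame:
    """Append numeric score and symbol columns to an observation table."""
    scores = df["percent"].map(score_percent)
    out = df.copy()
    out["score"] = [s.numeric for s in scores]
    out["score_symbol"] = [s.symbol for s in scores]
    return out


def plasma_cell_positivity_rate(df: pd.DataFrame) -> float:
    """Fraction of biopsies whose plasma cells stain positive (percent > 0).

    The "<25" borderline sentinel counts as positive. Expects exactly one
    plasma-cell observation per biopsy.
    """
    plasma = df[df["cell_type"] == "plasma_cells"]
    if plasma["biopsy_id"].duplicated().any():
        raise ValueError("more than one plasma-cell observation for a biopsy")
    if len(plasma) == 0:
        raise ValueError("no plasma-cell observations")
    positive = plasma["percent"].map(lambda p: p == BORDERLINE or float(p) > 0)
    return float(positive.mean())


def rater_agreement(
    ratings: Mapping[str, pd.DataFrame],
) -> tuple[dict[str, float], float, dict[str, int]]:
    """Percent agreement among raters, per variable and overall.

    Each rater contributes a biopsies x variables table of scores over an
    identical grid. Per variable: the mean over rater pairs of the fraction
    of biopsies with identical scores, times 100; overall: the unweighted
    mean over variables. Cells missing (NaN) for either rater of a pair are
    excluded pairwise; the per-variable count of excluded comparisons is
    returned alongside.
    """
    names = list(ratings)
    if len(names) < 2:
        raise ValueError("at least two raters required")
    first = ratings[names[0]]
    for name in names[1:]:
        other = ratings[name]
        if not first.index.equals(other.index) or not first.columns.equals(other.columns):
            raise ValueError(f"rater {name!r} grid differs from rater {names[0]!r}")

    per_variable: dict[str, float] = {}
    excluded: dict[str, int] = {}
    for var in first.columns:
        fracs = []
        n_excluded = 0
        for r1, r2 in combinations(names, 2):
            s1 = ratings[r1][var]
            s2 = ratings[r2][var]
            ok = s1.notna() & s2.notna()
            n_excluded += int((~ok).sum())
            if ok.sum() == 0:
                continue
            fracs.append(float((s1[ok] == s2[ok]).mean()))
        if not fracs:
            raise ValueError(f"variable {var!r}: no comparable cells between any rater pair")
        per_variable[var] = 100.0 * sum(fracs) / len(fracs)
        excluded[var] = n_excluded
    overall = sum(per_variable.values()) / len(per_variable)
    return per_variable, overall, excluded
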