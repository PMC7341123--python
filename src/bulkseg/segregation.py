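"""Mendelian segregation arithmetic for fertility-restoration genetics.

Plants are scored on a five-grade anther-exsertion/pollen-shed scale:
grades I-II are sterile, III-V fertile, and grade V is "fully fertile".
This module tabulates fertility-grade counts by population, environment
and restorer-marker genotype class, computes observed fertile:sterile
ratios, Pearson goodness-of-fit chi-square tests against theoretical
Mendelian ratios (1:2:1 for an F2 marker, 1:1 for a backcross; no
continuity correction), and per-genotype fully-fertile percentages.

Ratios and percentages are rounded half-up to two decimals for report
parity; raw doubles are kept alongside.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .simulate import GRADES, STERILE_GRADES, Individual

__all__ = [
    "classify",
    "observed_ratio",
    "format_ratio",
    "gof_chisq",
    "GofResult",
    "FertilityTable",
    "genotype_fertility_summary",
    "load_study_counts",
    "load_bc2_counts",
    "tabulate_population",
    "read_plant_csv",
]


def classify(grade: str) -> str:
    """Map a fertility grade to 'sterile' (I, II) or 'fertile' (III-V)."""
    if grade not in GRADES:
        raise DataError(f"unknown fertility grade {grade!r} (expected one of {GRADES})")
    return "sterile" if grade in STERILE_GRADES else "fertile"


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def observed_ratio(fertile: int, sterile: int, decimals: int = 2) -> float:
    """Fertile:sterile ratio, rounded half-up (e.g. 1213:33 -> 36.76)."""
    if sterile < 0 or fertile < 0:
        raise DataError("negative counts")
    if sterile == 0:
        raise DataError("all plants fertile; ratio undefined")
    return _round_half_up(fertile / sterile, decimals)


def format_ratio(fertile: int, sterile: int, decimals: int = 2) -> str:
    """Report form 'X.XX:1', or 'all fertile' when no sterile plants."""
    if sterile == 0:
        return "all fertile"
    return f"{observed_ratio(fertile, sterile, decimals):.{decimals}f}:1"


@dataclass(frozen=True)
class GofResult:
    """Pearson goodness-of-fit of observed class counts to a ratio."""

    observed: tuple[int, ...]
    ratio: tuple[float, ...]
    expected: tuple[float, ...]
    chi2: float
    df: int
    p_value: float


def gof_chisq(observed: Sequence[int], ratio: Sequence[float]) -> GofResult:
    """Pearson chi-square goodness-of-fit, no continuity correction.

    `ratio` gives positive theoretical weights (scale-invariant: 1:2:1
    and 2:4:2 are equivalent).  Expected counts are total * w_i / sum(w).
    """
    observed = tuple(int(x) for x in observed)
    ratio = tuple(float(w) for w in ratio)
    if len(observed) != len(ratio) or len(observed) < 2:
        raise ConfigError("observed counts and ratio weights must align, with >= 2 classes")
    if any(w <= 0 for w in ratio):
        raise ConfigError("ratio weights must be > 0")
    total = sum(observed)
    if total <= 0:
        raise DataError("no observations")
    expected = tuple(total * w / sum(ratio) for w in ratio)
    chi2, p = stats.chisquare(observed, f_exp=expected)
    return GofResult(
        observed=observed,
        ratio=ratio,
        expected=expected,
        chi2=float(chi2),
        df=len(observed) - 1,
        p_value=float(p),
    )


@dataclass
class FertilityTable:
    """Fertility-grade counts, optionally stratified by genotype class.

    `counts` has columns population, environment, genotype (optional; NA
    when unstratified) and one column per grade I-V.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [g for g in GRADES if g not in self.counts.columns]
        if missing:
            raise DataError(f"count table missing grade columns {missing}")
        if (self.counts[list(GRADES)].to_numpy() < 0).any():
            raise DataError("negative grade counts")

    def with_margins(self) -> pd.DataFrame:
        """Add total / fertile / sterile columns and the observed ratio."""
        df = self.counts.copy()
        df["fertile"] = df[["III", "IV", "V"]].sum(axis=1)
        df["sterile"] = df[["I", "II"]].sum(axis=1)
        df["total"] = df["fertile"] + df["sterile"]
        df["observed_ratio"] = [
            format_ratio(f, s) for f, s in zip(df["fertile"], df["sterile"])
        ]
        return df

    def pooled(self, by: Sequence[str] = ("population",)) -> pd.DataFrame:
        """Sum grade counts over everything except `by`."""
        g = self.counts.groupby(list(by), sort=False)[list(GRADES)].sum().reset_index()
        return FertilityTable(g).with_margins()


def genotype_fertility_summary(table: FertilityTable, decimals: int = 2) -> pd.DataFrame:
    """Per-genotype fertile/sterile counts and fully-fertile percentage.

    The percentage is the grade-V share of the class total, rounded
    half-up; NA for empty classes.  Genotype strata are pooled over
    environments within each population.
    """
    if "genotype" not in table.counts.columns or table.counts["genotype"].isna().all():
        raise DataError("genotype-stratified table required")
    g = (
        table.counts.groupby(["population", "genotype"], sort=False)[list(GRADES)]
        .sum()
        .reset_index()
    )
    g["fertile"] = g[["III", "IV", "V"]].sum(axis=1)
    g["sterile"] = g[["I", "II"]].sum(axis=1)
    g["total"] = g["fertile"] + g["sterile"]
    g["pct_fully_fertile"] = [
        _round_half_up(100 * v / t, decimals) if t > 0 else np.nan
        for v, t in zip(g["V"], g["total"])
    ]
    return g


def tabulate_population(
    plants: Sequence[Individual],
    genome=None,
    model=None,
    environment: str = "sim",
) -> FertilityTable:
    """Build a FertilityTable from simulated plants.

    With `genome` and `model` given, plants are stratified by their
    restorer-marker genotype class (Rf4Rf4 / Rf4rf4 / rf4rf4).
    """
    rows: dict[tuple, dict] = {}
    for p in plants:
        if genome is not None and model is not None:
            dosage = int(p.dosage(genome, *model.rf4_locus))
            geno = {0: "rf4rf4", 1: "Rf4rf4", 2: "Rf4Rf4"}[dosage]
        else:
            geno = pd.NA
        key = (p.population, environment, geno)
        row = rows.setdefault(key, {g: 0 for g in GRADES})
        row[p.grade] += 1
    out = pd.DataFrame(
        [
            {"population": k[0], "environment": k[1], "genotype": k[2], **v}
            for k, v in rows.items()
        ]
    )
    return FertilityTable(out)


def read_plant_csv(path) -> FertilityTable:
    """Read a plant-level CSV (plant_id, population, environment, grade,
    genotype) into a grade-count table."""
    df = pd.read_csv(path)
    required = {"population", "environment", "grade"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"plant CSV missing columns {sorted(missing)}")
    bad = set(df["grade"]) - set(GRADES)
    if bad:
        raise DataError(f"unknown fertility grades {sorted(bad)}")
    if "genotype" not in df.columns:
        df["genotype"] = pd.NA
    piv = (
        df.pivot_table(
            index=["population", "environment", "genotype"],
            columns="grade",
            aggfunc="size",
            fill_value=0,
            dropna=False,
        )
        .reindex(columns=list(GRADES), fill_value=0)
        .reset_index()
    )
    piv.columns.name = None
    return FertilityTable(piv)


def load_study_counts() -> FertilityTable:
    """Grade x Rf4-marker-genotype counts for the (CHuangzaosi x A619) F2
    and BC1F1 populations scored at Chengdu and Jinghong (2018)."""
    ref = importlib.resources.files("bulkseg") / "data" / "chz_a619_fertility_counts.tsv"
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t")
    return FertilityTable(df)


def load_bc2_counts() -> dict[str, int]:
    """Coarse counts for BC2F1 progenies of fully restored rf4rf4 plants
    (total, sterile, grade-V, grade-III/IV)."""
    ref = importlib.resources.files("bulkseg") / "data" / "bc2f1_from_restored_rf4rf4.tsv"
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t")
    row = df.iloc[0]
    return {
        "total": int(row["total"]),
        "sterile": int(row["sterile"]),
        "grade_V": int(row["grade_V"]),
        "grade_III_IV": int(row["grade_III_IV"]),
    }
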