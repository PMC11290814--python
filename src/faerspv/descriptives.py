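"""Descriptive frequency tables for a deduplicated report corpus.

Covers the usual demography-and-seriousness summary of a pharmacovigilance
case series: gender, integer-year age bands (≤19, 20–39, 40–59, 60–79, ≥80,
unknown; both printed endpoints inclusive, fractional ages floored), the
top-k reporting countries, and the four serious-outcome categories (death,
disability, hospitalization, life-threatening).  Outcome categories are not
mutually exclusive — a case counts once in every category it carries — and
all percentages use the grand total of cases as denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .contingency import ROLE_PRIMARY_SUSPECT
from .faers_io import ReportCorpus

AGE_BANDS: tuple[tuple[str, float, float], ...] = (
    ("<=19", -math.inf, 19),
    ("20-39", 20, 39),
    ("40-59", 40, 59),
    ("60-79", 60, 79),
    (">=80", 80, math.inf),
)

#: FAERS outcome code → headline serious-outcome category.
OUTCOME_CATEGORIES = {
    "HO": "hospitalization",
    "DE": "death",
    "LT": "life-threatening",
    "DS": "disability",
}
#: Codes reported in an "other" row, outside the four headline categories.
OTHER_OUTCOME_CODES = ("CA", "RI", "OT")


@dataclass(frozen=True)
class FrequencyTable:
    """Counts with percentages of a fixed grand total (2 dp)."""

    labels: tuple[str, ...]
    counts: tuple[int, ...]
    total: int

    def __post_init__(self):
        if len(self.labels) != len(self.counts):
            raise ValueError("labels and counts must align")
        if any(c < 0 for c in self.counts) or self.total < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def percentages(self) -> tuple[float, ...]:
        if self.total == 0:
            return tuple(math.nan for _ in self.counts)
        return tuple(round(100.0 * c / self.total, 2) for c in self.counts)

    def percentage_of(self, label: str) -> float:
        return self.percentages[self.labels.index(label)]

    def to_frame(self, name: str = "category") -> pd.DataFrame:
        return pd.DataFrame({name: self.labels, "count": self.counts, "percentage": self.percentages})


def age_band(age_years: float | None) -> str:
    """Band label for an age in years; NaN/None → ``"unknown"``."""
    if age_years is None or (isinstance(age_years, float) and math.isnan(age_years)):
        return "unknown"
    whole = math.floor(age_years)
    for label, lo, hi in AGE_BANDS:
        if lo <= whole <= hi:
            return label
    return "unknown"


def demographics_summary(corpus: ReportCorpus, top_countries: int = 6) -> dict[str, FrequencyTable]:
    """Gender, age-band and top-country frequency tables.

    Gender and age are exhaustive partitions (counts sum to the corpus
    size); the country table lists only the ``top_countries`` most frequent
    reporting countries, still as percentages of the grand total.
    """
    total = corpus.n_cases
    demo = corpus.demo

    gender_labels = ("male", "female", "unknown")
    gender_counts = tuple(int((demo["gender"] == g).sum()) for g in gender_labels)

    bands = demo["age_years"].map(age_band)
    band_labels = tuple(label for label, _, _ in AGE_BANDS) + ("unknown",)
    band_counts = tuple(int((bands == label).sum()) for label in band_labels)

    country = demo["country"].astype("string").str.strip()
    country = country[country.notna() & (country != "")]
    top = country.value_counts().iloc[:top_countries]
    # value_counts ties are broken by label order of appearance; make it stable
    top = top.sort_values(ascending=False, kind="mergesort")

    return {
        "gender": FrequencyTable(gender_labels, gender_counts, total),
        "age": FrequencyTable(band_labels, band_counts, total),
        "country": FrequencyTable(tuple(top.index), tuple(int(v) for v in top.values), total),
    }


def outcomes_summary(corpus: ReportCorpus, include_other: bool = True) -> FrequencyTable:
    """Serious-outcome frequency table (one count per case per category)."""
    total = corpus.n_cases
    oc = corpus.outcomes
    labels: list[str] = []
    counts: list[int] = []
    for code in ("HO", "DE", "LT", "DS"):
        labels.append(OUTCOME_CATEGORIES[code])
        counts.append(int(oc.loc[oc["outcome"] == code, "case_id"].nunique()))
    if include_other:
        labels.append("other")
        counts.append(int(oc.loc[oc["outcome"].isin(OTHER_OUTCOME_CODES), "case_id"].nunique()))
    return FrequencyTable(tuple(labels), tuple(counts), total)


def report_counts(
    corpus: ReportCorpus,
    drug: str | None = None,
    role_filter: Iterable[str] = ROLE_PRIMARY_SUSPECT,
) -> dict[str, int]:
    """Case-level and pair-level corpus counts, side by side.

    Spontaneous-reporting summaries mix counting units freely (cases,
    distinct event terms, drug-linked terms); this returns them all so a
    report can state explicitly which is which.
    """
    out = {
        "cases": corpus.n_cases,
        "distinct_pts": int(corpus.reactions["pt_code"].nunique()),
        "distinct_socs": int(corpus.reactions["soc_code"].nunique()),
    }
    if drug is not None:
        role_filter = frozenset(role_filter)
        d = corpus.drugs
        exposed = set(d.loc[(d["concept"] == drug) & d["role"].isin(role_filter), "case_id"])
        reac = corpus.reactions[corpus.reactions["case_id"].isin(exposed)]
        out.update({
            "drug_cases": len(exposed),
            "drug_pts": int(reac["pt_code"].nunique()),
            "drug_socs": int(reac["soc_code"].nunique()),
            "drug_case_pt_pairs": int(len(reac[["case_id", "pt_code"]].drop_duplicates())),
        })
    return out


def summaries_to_frame(
    demographics: dict[str, FrequencyTable], outcomes: FrequencyTable, total: int
) -> pd.DataFrame:
    """Single long-format frame of all descriptive tables (report layout)."""
    blocks = [("number of events", FrequencyTable(("total",), (total,), total))]
    blocks += [(k, v) for k, v in demographics.items()]
    blocks.append(("serious outcomes", outcomes))
    rows = []
    for section, table in blocks:
        for label, count, pct in zip(table.labels, table.counts, table.percentages):
            rows.append({"section": section, "category": label, "count": count, "percentage": pct})
    return pd.DataFrame(rows, columns=["section", "category", "count", "percentage"])
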