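"""2×2 contingency tables for drug–event pairs.

Disproportionality analysis of a spontaneous reporting system has no exposure
denominator, so every statistic is computed from the report-level 2×2 table

====================  ============  ================
..                    target event  other events
====================  ============  ================
target drug           a             b
all other drugs       c             d
====================  ============  ================

with N = a+b+c+d the corpus size.  The counting unit is the unique case: a
case is drug-exposed iff it carries a mention of the target concept with a
role code in ``role_filter`` (default: primary suspect only), and it counts
in the event column once no matter how many of its PTs match the event (or,
at SOC level, map into the target SOC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .faers_io import MedDRAHierarchy, ReportCorpus

LEVELS = ("PT", "SOC")
#: Default exposure definition: primary-suspect mentions only.
ROLE_PRIMARY_SUSPECT = frozenset({"PS"})
ROLE_ALL = frozenset({"PS", "SS", "C", "I"})


@dataclass(frozen=True)
class ContingencyTable:
    """Counts a, b, c, d for one (drug, event) pair at one MedDRA level."""

    a: int
    b: int
    c: int
    d: int
    drug: str = ""
    event: str = ""
    level: str = "PT"
    event_name: str = ""

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"cell {name}={v!r} must be a nonnegative integer")
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def swapped(self) -> "ContingencyTable":
        """Table with target and comparator drug exchanged: (a,b,c,d)→(c,d,a,b)."""
        return ContingencyTable(self.c, self.d, self.a, self.b, drug=f"non-{self.drug}",
                                event=self.event, level=self.level, event_name=self.event_name)


def _exposed_ids(corpus: ReportCorpus, drug: str, role_filter: frozenset) -> set:
    d = corpus.drugs
    mask = (d["concept"] == drug) & d["role"].isin(role_filter)
    return set(d.loc[mask, "case_id"])


def _event_ids(corpus: ReportCorpus, event: str, level: str) -> set:
    col = "soc_code" if level == "SOC" else "pt_code"
    r = corpus.reactions
    return set(r.loc[r[col] == str(event), "case_id"])


def build_table(
    corpus: ReportCorpus,
    drug: str,
    event: str,
    level: str = "PT",
    role_filter: Iterable[str] = ROLE_PRIMARY_SUSPECT,
    event_name: str = "",
) -> ContingencyTable:
    """Build the 2×2 table for one (drug, event) pair.

    A drug absent from the corpus yields a table with a=b=0 plus a warning;
    an empty corpus raises ``ValueError``.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    n_total = corpus.n_cases
    if n_total == 0:
        raise ValueError("empty corpus: N=0")
    role_filter = frozenset(role_filter)
    exposed = _exposed_ids(corpus, drug, role_filter)
    if not exposed:
        warnings.warn(f"drug {drug!r} (roles {sorted(role_filter)}) absent from corpus", stacklevel=2)
    with_event = _event_ids(corpus, event, level)
    a = len(exposed & with_event)
    b = len(exposed) - a
    c = len(with_event) - a
    d = n_total - a - b - c
    return ContingencyTable(a, b, c, d, drug=drug, event=str(event), level=level, event_name=event_name)


def all_event_tables(
    corpus: ReportCorpus,
    drug: str,
    level: str = "PT",
    role_filter: Iterable[str] = ROLE_PRIMARY_SUSPECT,
    min_a: int = 1,
    hierarchy: MedDRAHierarchy | None = None,
) -> list[ContingencyTable]:
    """One table per event observed among exposed cases with a ≥ ``min_a``.

    Sorted by a descending, ties by event code ascending.  ``hierarchy``
    (optional) decorates tables with event names.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    n_total = corpus.n_cases
    if n_total == 0:
        raise ValueError("empty corpus: N=0")
    role_filter = frozenset(role_filter)
    exposed = _exposed_ids(corpus, drug, role_filter)
    if not exposed:
        warnings.warn(f"drug {drug!r} (roles {sorted(role_filter)}) absent from corpus", stacklevel=2)
        return []
    col = "soc_code" if level == "SOC" else "pt_code"
    reac = corpus.reactions
    a_counts = (
        reac.loc[reac["case_id"].isin(exposed)]
        .groupby(col)["case_id"].nunique()
    )
    total_counts = reac.groupby(col)["case_id"].nunique()
    n_exposed = len(exposed)
    tables = []
    for event, a in a_counts.items():
        if a < min_a:
            continue
        c = int(total_counts[event]) - int(a)
        b = n_exposed - int(a)
        d = n_total - int(a) - b - c
        name = hierarchy.event_name(event, level) if hierarchy is not None else ""
        tables.append(ContingencyTable(int(a), b, c, d, drug=drug, event=str(event), level=level, event_name=name))
    tables.sort(key=lambda t: (-t.a, t.event))
    return tables


def tables_to_frame(tables: Iterable[ContingencyTable]) -> pd.DataFrame:
    """CSV-ready frame of (drug, event_code, event_name, level, a, b, c, d)."""
    rows = [
        {"drug": t.drug, "event_code": t.event, "event_name": t.event_name,
         "level": t.level, "a": t.a, "b": t.b, "c": t.c, "d": t.d}
        for t in tables
    ]
    return pd.DataFrame(rows, columns=["drug", "event_code", "event_name", "level", "a", "b", "c", "d"])
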