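"""The four disproportionality statistics and their positivity criteria.

For a 2×2 table (a, b, c, d), N = a+b+c+d:

* ROR  = ad/(bc), 95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d));
  positive when the CI lower bound > 1 and a ≥ 3.
* PRR  = a(c+d)/(c(a+b)) with the 1-df Pearson statistic
  χ² = N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) (no continuity correction);
  positive when PRR ≥ 2, χ² ≥ 4 and a ≥ 3.  The 95% CI uses the
  delta-method log-PRR dispersion √(1/a − 1/(a+b) + 1/c − 1/(c+d)).
* IC   = log2(aN/((a+b)(a+c))), the information component of the BCPNN
  family; 95% CI = IC ± 2·√V(IC); positive when IC025 (the lower bound) > 0.
* EBGM = aN/((a+b)(a+c)), the relative reporting ratio, with
  95% CI = exp(ln EBGM ± 1.96·√(1/a+1/b+1/c+1/d)); positive when EBGM05
  (the lower bound) > 2.

IC and EBGM are the same observed-to-expected ratio on different scales, so
``ic.point == log2(ebgm.point)`` holds identically; this is asserted by the
test suite at machine precision.  No Bayesian shrinkage is applied — EBGM
here is the plain relative reporting ratio, not the MGPS posterior mean.

V(IC) has no single canonical form; the default (``"delta-log2"``) reuses
the Woolf dispersion 1/a+1/b+1/c+1/d of the other intervals, rescaled to
log2 units: V(IC) = (1/ln 2)²·(1/a+1/b+1/c+1/d).  The strategy hook exists
so a Bayesian BCPNN variance can be added without touching callers.

Tables with a zero cell yield a flagged-undefined result (NaN estimates,
``zero_cell=True``) that always classifies negative; a Haldane–Anscombe
+0.5 correction can be opted into via ``zero_cell="haldane"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .contingency import ContingencyTable, ROLE_PRIMARY_SUSPECT, all_event_tables
from .faers_io import MedDRAHierarchy, ReportCorpus

_Z95 = 1.96
_LN2 = math.log(2.0)

ZERO_CELL_STRATEGIES = ("flag", "haldane")


@dataclass(frozen=True)
class EstimateCI:
    """Point estimate with 95% interval; ``zero_cell`` marks undefined results."""

    point: float
    lower95: float
    upper95: float
    zero_cell: bool = False

    @property
    def defined(self) -> bool:
        return not self.zero_cell and math.isfinite(self.point)


_UNDEFINED = EstimateCI(math.nan, math.nan, math.nan, zero_cell=True)


def _cells(t: ContingencyTable, zero_cell: str) -> tuple[float, float, float, float] | None:
    if zero_cell not in ZERO_CELL_STRATEGIES:
        raise ValueError(f"zero_cell must be one of {ZERO_CELL_STRATEGIES}")
    a, b, c, d = t.cells
    if min(a, b, c, d) > 0:
        return float(a), float(b), float(c), float(d)
    if zero_cell == "haldane":
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return None


def _woolf_se(a: float, b: float, c: float, d: float) -> float:
    return math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


def _log_ci(point: float, se: float) -> tuple[float, float]:
    ln = math.log(point)
    return math.exp(ln - _Z95 * se), math.exp(ln + _Z95 * se)


def ror_stat(t: ContingencyTable, zero_cell: str = "flag") -> EstimateCI:
    """Reporting odds ratio ad/(bc) with Woolf 95% CI."""
    cells = _cells(t, zero_cell)
    if cells is None:
        return _UNDEFINED
    a, b, c, d = cells
    point = (a * d) / (b * c)
    lo, hi = _log_ci(point, _woolf_se(a, b, c, d))
    return EstimateCI(point, lo, hi)


def chi2_stat(t: ContingencyTable) -> float:
    """1-df Pearson χ² on the raw cells, no continuity correction."""
    a, b, c, d = (float(x) for x in t.cells)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return math.nan
    return n * (a * d - b * c) ** 2 / denom


def prr_stat(t: ContingencyTable, zero_cell: str = "flag") -> tuple[EstimateCI, float]:
    """Proportional reporting ratio with delta-method 95% CI, plus χ².

    χ² is always computed from the raw integer cells (the Haldane option
    affects only the ratio and its interval).
    """
    chi2 = chi2_stat(t)
    cells = _cells(t, zero_cell)
    if cells is None:
        return _UNDEFINED, chi2
    a, b, c, d = cells
    point = (a * (c + d)) / (c * (a + b))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    lo, hi = _log_ci(point, se)
    return EstimateCI(point, lo, hi), chi2


def _vic_delta_log2(a: float, b: float, c: float, d: float) -> float:
    return (1 / a + 1 / b + 1 / c + 1 / d) / (_LN2 ** 2)


#: Selectable V(IC) strategies (name → callable on the four cells).
VIC_STRATEGIES: dict[str, Callable[[float, float, float, float], float]] = {
    "delta-log2": _vic_delta_log2,
}


def ic_stat(t: ContingencyTable, vic: str = "delta-log2", zero_cell: str = "flag") -> EstimateCI:
    """Information component log2(aN/((a+b)(a+c))); lower95 is IC025."""
    try:
        vic_fn = VIC_STRATEGIES[vic]
    except KeyError:
        raise ValueError(f"unknown V(IC) strategy {vic!r}; choose from {sorted(VIC_STRATEGIES)}") from None
    cells = _cells(t, zero_cell)
    if cells is None:
        return _UNDEFINED
    a, b, c, d = cells
    n = a + b + c + d
    point = math.log2(a * n / ((a + b) * (a + c)))
    half = 2.0 * math.sqrt(vic_fn(a, b, c, d))
    return EstimateCI(point, point - half, point + half)


def ic_from_rrr(rrr: float) -> float:
    """IC point implied by a relative reporting ratio: IC = log2(RRR).

    IC and EBGM are the same observed/expected ratio aN/((a+b)(a+c)) on
    log2 and natural scales, so either determines the other exactly.
    """
    return math.log2(rrr)


def ebgm_stat(t: ContingencyTable, zero_cell: str = "flag") -> EstimateCI:
    """Relative reporting ratio aN/((a+b)(a+c)); lower95 is EBGM05."""
    cells = _cells(t, zero_cell)
    if cells is None:
        return _UNDEFINED
    a, b, c, d = cells
    n = a + b + c + d
    point = a * n / ((a + b) * (a + c))
    lo, hi = _log_ci(point, _woolf_se(a, b, c, d))
    return EstimateCI(point, lo, hi)


@dataclass(frozen=True)
class SignalStats:
    """All four statistics for one table."""

    table: ContingencyTable
    ror: EstimateCI
    prr: EstimateCI
    chi2: float
    ic: EstimateCI
    ebgm: EstimateCI


@dataclass(frozen=True)
class SignalFlags:
    """Per-algorithm positivity decisions."""

    ror_positive: bool
    prr_positive: bool
    bcpnn_positive: bool
    ebgm_positive: bool

    @property
    def any_positive(self) -> bool:
        return self.ror_positive or self.prr_positive or self.bcpnn_positive or self.ebgm_positive

    @property
    def all_positive(self) -> bool:
        return self.ror_positive and self.prr_positive and self.bcpnn_positive and self.ebgm_positive


def compute_stats(
    t: ContingencyTable, vic: str = "delta-log2", zero_cell: str = "flag"
) -> SignalStats:
    prr, chi2 = prr_stat(t, zero_cell)
    return SignalStats(
        table=t,
        ror=ror_stat(t, zero_cell),
        prr=prr,
        chi2=chi2,
        ic=ic_stat(t, vic, zero_cell),
        ebgm=ebgm_stat(t, zero_cell),
    )


def classify(s: SignalStats) -> SignalFlags:
    """Apply the four positivity criteria; undefined statistics are negative.

    The case-count floor N ≥ 3 is read as the drug–event cell a ≥ 3 (the
    conventional reading in disproportionality practice) and applies to the
    ROR and PRR criteria.
    """
    a = s.table.a
    ror_pos = s.ror.defined and s.ror.lower95 > 1.0 and a >= 3
    prr_pos = (
        s.prr.defined
        and math.isfinite(s.chi2)
        and s.prr.point >= 2.0
        and s.chi2 >= 4.0
        and a >= 3
    )
    bcpnn_pos = s.ic.defined and s.ic.lower95 > 0.0
    ebgm_pos = s.ebgm.defined and s.ebgm.lower95 > 2.0
    return SignalFlags(ror_pos, prr_pos, bcpnn_pos, ebgm_pos)


_SIGNAL_COLUMNS = [
    "event_code", "event_name", "level", "case_reports",
    "ror", "ror_lower95", "ror_upper95",
    "prr", "prr_lower95", "prr_upper95", "chi2",
    "ic", "ic025", "ic975",
    "ebgm", "ebgm05", "ebgm95",
    "ror_positive", "prr_positive", "bcpnn_positive", "ebgm_positive",
    "any_positive", "all_positive",
]


def signal_table(
    corpus: ReportCorpus,
    drug: str,
    level: str = "SOC",
    role_filter: Iterable[str] = ROLE_PRIMARY_SUSPECT,
    min_a: int = 1,
    hierarchy: MedDRAHierarchy | None = None,
    vic: str = "delta-log2",
    zero_cell: str = "flag",
    sort_by: str = "case_reports",
) -> pd.DataFrame:
    """Ranked per-event statistics for one drug at one MedDRA level.

    One row per event with a ≥ ``min_a``; columns carry the case count, the
    four estimates with their 95% bounds, χ² and the positivity flags.
    Default ranking is by case count descending; ``sort_by="ebgm"`` ranks by
    EBGM descending instead (ties by event code in both orders).
    """
    if sort_by not in ("case_reports", "ebgm"):
        raise ValueError("sort_by must be 'case_reports' or 'ebgm'")
    rows = []
    for t in all_event_tables(corpus, drug, level, role_filter, min_a, hierarchy):
        s = compute_stats(t, vic, zero_cell)
        f = classify(s)
        rows.append({
            "event_code": t.event, "event_name": t.event_name, "level": t.level,
            "case_reports": t.a,
            "ror": s.ror.point, "ror_lower95": s.ror.lower95, "ror_upper95": s.ror.upper95,
            "prr": s.prr.point, "prr_lower95": s.prr.lower95, "prr_upper95": s.prr.upper95,
            "chi2": s.chi2,
            "ic": s.ic.point, "ic025": s.ic.lower95, "ic975": s.ic.upper95,
            "ebgm": s.ebgm.point, "ebgm05": s.ebgm.lower95, "ebgm95": s.ebgm.upper95,
            "ror_positive": f.ror_positive, "prr_positive": f.prr_positive,
            "bcpnn_positive": f.bcpnn_positive, "ebgm_positive": f.ebgm_positive,
            "any_positive": f.any_positive, "all_positive": f.all_positive,
        })
    frame = pd.DataFrame(rows, columns=_SIGNAL_COLUMNS)
    if frame.empty:
        return frame
    if sort_by == "ebgm":
        frame = frame.sort_values(["ebgm", "event_code"], ascending=[False, True],
                                  kind="mergesort", na_position="last")
    else:
        frame = frame.sort_values(["case_reports", "event_code"], ascending=[False, True],
                                  kind="mergesort")
    return frame.reset_index(drop=True)


def format_signal_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Report-style rendering: ratios as 'point (lower-upper)', 2 decimals."""

    def fmt(x: float) -> str:
        return "" if not np.isfinite(x) else f"{round(x, 2):g}"

    out = pd.DataFrame({
        "event_code": frame["event_code"],
        "event_name": frame["event_name"],
        "case_reports": frame["case_reports"],
        "ROR (95%CI)": [f"{fmt(p)} ({fmt(l)}-{fmt(u)})" for p, l, u in
                        zip(frame["ror"], frame["ror_lower95"], frame["ror_upper95"])],
        "PRR (95%CI)": [f"{fmt(p)} ({fmt(l)}-{fmt(u)})" for p, l, u in
                        zip(frame["prr"], frame["prr_lower95"], frame["prr_upper95"])],
        "chi2": [fmt(x) for x in frame["chi2"]],
        "IC (IC025)": [f"{fmt(p)} ({fmt(l)})" for p, l in zip(frame["ic"], frame["ic025"])],
        "EBGM (EBGM05)": [f"{fmt(p)} ({fmt(l)})" for p, l in zip(frame["ebgm"], frame["ebgm05"])],
    })
    return out
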