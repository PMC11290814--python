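"""Ingest of FAERS-style quarterly ASCII extracts.

The FDA Adverse Event Reporting System distributes each quarter as a set of
``$``-delimited ASCII tables (DEMO, DRUG, REAC, OUTC) keyed by a case
identifier plus a case version.  Cases are resubmitted across quarters as new
versions, so a multi-quarter analysis must keep exactly one record per case.
This module parses that dialect, normalises verbatim drug names against a
synonym dictionary (RxNorm-style concept ids), maps MedDRA preferred terms
(PTs) to their primary System Organ Class (SOC), deduplicates case versions
and assembles an analysis-ready :class:`ReportCorpus`.

The deduplication rule — keep the record with the latest receipt date, break
ties by the larger case version, then by later file order — is the
conventional rule for FAERS analyses and is deterministic for a fixed input.
"""

from __future__ import annotations

import logging
import re
import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel concept id for verbatim drug names absent from the dictionary.
UNMAPPED = "UNMAPPED"
#: Bucket code for reactions whose PT is not in the hierarchy (opt-in).
UNKNOWN_PT = "UNKNOWN"

ROLE_CODES = ("PS", "SS", "C", "I")
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

#: Conversion factors from FAERS age units to years.
AGE_UNIT_YEARS = {
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

_GENDER_MAP = {"M": "male", "F": "female"}

DEMO_COLUMNS = ("primaryid", "caseid", "caseversion", "fda_dt", "sex", "age", "age_cod", "occr_country")
DRUG_COLUMNS = ("primaryid", "caseid", "drug_seq", "role_cod", "drugname")
REAC_COLUMNS = ("primaryid", "caseid", "pt")
OUTC_COLUMNS = ("primaryid", "caseid", "outc_cod")


class UnknownPTError(KeyError):
    """A reaction PT is absent from the MedDRA hierarchy."""


@dataclass(frozen=True)
class FaersDialect:
    """File-layout parameters of a quarterly extract directory."""

    delimiter: str = "$"
    demo_pattern: str = "DEMO*.txt"
    drug_pattern: str = "DRUG*.txt"
    reac_pattern: str = "REAC*.txt"
    outc_pattern: str = "OUTC*.txt"
    date_format: str = "%Y%m%d"


DEFAULT_DIALECT = FaersDialect()


@dataclass
class RawQuarter:
    """Parsed but otherwise untouched tables of one quarterly extract."""

    demo_rows: pd.DataFrame
    drug_rows: pd.DataFrame
    reac_rows: pd.DataFrame
    outc_rows: pd.DataFrame
    source: str = ""
    malformed: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        known = set(self.demo_rows["caseid"])
        for name, frame in (("DRUG", self.drug_rows), ("REAC", self.reac_rows), ("OUTC", self.outc_rows)):
            orphans = set(frame["caseid"]) - known
            if orphans:
                raise ValueError(
                    f"{name} table of {self.source or 'quarter'} references case ids "
                    f"absent from DEMO: {sorted(orphans)[:5]} ({len(orphans)} total)"
                )


@dataclass(frozen=True)
class CaseReport:
    """One deduplicated safety report."""

    case_id: str
    receipt_date: pd.Timestamp | None
    gender: str
    age_years: float | None
    country: str | None
    drugs: frozenset  # of (concept_id, role_code)
    reactions: frozenset  # of pt_code
    outcomes: frozenset  # of outcome code


@dataclass
class ReportCorpus:
    """Deduplicated, normalised corpus backing all downstream analyses.

    Tabular (long) layout rather than per-case objects so that contingency
    counting stays vectorised on large corpora; :meth:`case_report` and
    :meth:`iter_cases` materialise individual :class:`CaseReport` records.
    """

    demo: pd.DataFrame       # case_id, receipt_date, gender, age_years, country
    drugs: pd.DataFrame      # case_id, concept, role
    reactions: pd.DataFrame  # case_id, pt_code, soc_code
    outcomes: pd.DataFrame   # case_id, outcome
    log: dict = field(default_factory=dict)

    @property
    def n_cases(self) -> int:
        return len(self.demo)

    @property
    def case_ids(self) -> pd.Series:
        return self.demo["case_id"]

    def case_report(self, case_id: str) -> CaseReport:
        row = self.demo.loc[self.demo["case_id"] == case_id]
        if row.empty:
            raise KeyError(case_id)
        row = row.iloc[0]
        dr = self.drugs.loc[self.drugs["case_id"] == case_id]
        re_ = self.reactions.loc[self.reactions["case_id"] == case_id]
        oc = self.outcomes.loc[self.outcomes["case_id"] == case_id]
        age = row["age_years"]
        return CaseReport(
            case_id=case_id,
            receipt_date=row["receipt_date"] if pd.notna(row["receipt_date"]) else None,
            gender=row["gender"],
            age_years=float(age) if pd.notna(age) else None,
            country=row["country"] if pd.notna(row["country"]) and row["country"] != "" else None,
            drugs=frozenset(zip(dr["concept"], dr["role"])),
            reactions=frozenset(re_["pt_code"]),
            outcomes=frozenset(oc["outcome"]),
        )

    def iter_cases(self) -> Iterator[CaseReport]:
        for cid in self.demo["case_id"]:
            yield self.case_report(cid)

    def to_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.demo.to_csv(outdir / "corpus_demo.csv", index=False)
        self.drugs.to_csv(outdir / "corpus_drugs.csv", index=False)
        self.reactions.to_csv(outdir / "corpus_reactions.csv", index=False)
        self.outcomes.to_csv(outdir / "corpus_outcomes.csv", index=False)

    @classmethod
    def from_csv(cls, indir: str | Path) -> "ReportCorpus":
        indir = Path(indir)
        demo = pd.read_csv(indir / "corpus_demo.csv", dtype={"case_id": str})
        demo["receipt_date"] = pd.to_datetime(demo["receipt_date"], errors="coerce")
        return cls(
            demo=demo,
            drugs=pd.read_csv(indir / "corpus_drugs.csv", dtype=str),
            reactions=pd.read_csv(indir / "corpus_reactions.csv", dtype=str),
            outcomes=pd.read_csv(indir / "corpus_outcomes.csv", dtype=str),
        )


class MedDRAHierarchy:
    """PT→SOC fragment of the MedDRA terminology.

    Holds the preferred terms, the System Organ Classes and the many-to-one
    primary-SOC assignment.  Lookup is by PT code or (case-insensitively) by
    PT name, since FAERS REAC tables carry verbatim PT names.
    """

    def __init__(self, pt_terms: pd.DataFrame, soc_terms: pd.DataFrame):
        pt_terms = pt_terms.astype({"pt_code": str, "soc_code": str})
        soc_terms = soc_terms.astype({"soc_code": str})
        if soc_terms["soc_code"].duplicated().any():
            raise ValueError("duplicate SOC codes in hierarchy")
        if pt_terms["pt_code"].duplicated().any():
            raise ValueError("a PT must map to exactly one primary SOC")
        missing = set(pt_terms["soc_code"]) - set(soc_terms["soc_code"])
        if missing:
            raise ValueError(f"PTs reference unknown SOC codes: {sorted(missing)}")
        self.pt_terms = pt_terms.reset_index(drop=True)
        self.soc_terms = soc_terms.reset_index(drop=True)
        self._pt_to_soc = dict(zip(pt_terms["pt_code"], pt_terms["soc_code"]))
        self._name_to_code = {n.strip().casefold(): c for n, c in zip(pt_terms["pt_name"], pt_terms["pt_code"])}
        self._pt_names = dict(zip(pt_terms["pt_code"], pt_terms["pt_name"]))
        self._soc_names = dict(zip(soc_terms["soc_code"], soc_terms["soc_name"]))

    @classmethod
    def from_csv(cls, pt_path: str | Path, soc_path: str | Path) -> "MedDRAHierarchy":
        return cls(pd.read_csv(pt_path, dtype=str), pd.read_csv(soc_path, dtype=str))

    @classmethod
    def default(cls) -> "MedDRAHierarchy":
        """Synthetic stand-in hierarchy shipped with the package (MedDRA is licensed)."""
        data = resources.files("faerspv") / "data"
        return cls.from_csv(data / "synthetic_meddra_pt.csv", data / "synthetic_meddra_soc.csv")

    def soc_of(self, pt_code: str) -> str:
        try:
            return self._pt_to_soc[str(pt_code)]
        except KeyError:
            raise UnknownPTError(f"PT code {pt_code!r} not in hierarchy") from None

    def pt_code_of(self, pt_name: str) -> str:
        try:
            return self._name_to_code[pt_name.strip().casefold()]
        except KeyError:
            raise UnknownPTError(f"PT name {pt_name!r} not in hierarchy") from None

    def pt_name(self, pt_code: str) -> str:
        return self._pt_names.get(str(pt_code), str(pt_code))

    def soc_name(self, soc_code: str) -> str:
        return self._soc_names.get(str(soc_code), str(soc_code))

    def event_name(self, code: str, level: str) -> str:
        return self.soc_name(code) if level == "SOC" else self.pt_name(code)


class DrugDictionary:
    """Synonym → concept-id map for verbatim drug-name normalisation."""

    def __init__(self, mapping: Mapping[str, str]):
        self.mapping = {canonical_drug_name(k): v for k, v in mapping.items()}

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugDictionary":
        frame = pd.read_csv(path, dtype=str)
        return cls(dict(zip(frame["synonym"], frame["concept_id"])))

    @classmethod
    def default(cls) -> "DrugDictionary":
        """Synthetic stand-in dictionary shipped with the package."""
        return cls.from_csv(resources.files("faerspv") / "data" / "synthetic_drug_dictionary.csv")

    def normalize(self, verbatim: str) -> str:
        return normalize_drug_name(verbatim, self.mapping)

    def synonyms_of(self, concept: str) -> list[str]:
        return [s for s, c in self.mapping.items() if c == concept]


def canonical_drug_name(verbatim: str) -> str:
    """Trim, collapse internal whitespace, strip edge punctuation, uppercase."""
    s = re.sub(r"\s+", " ", str(verbatim).strip())
    return s.strip(string.punctuation + " ").upper()


def normalize_drug_name(verbatim: str, dictionary: Mapping[str, str]) -> str:
    """Map a verbatim drug name to its concept id, or :data:`UNMAPPED`."""
    return dictionary.get(canonical_drug_name(verbatim), UNMAPPED)


def map_pt_to_soc(pt: str, hierarchy: MedDRAHierarchy) -> str:
    """Primary SOC code of a PT code; raises :class:`UnknownPTError` if absent."""
    return hierarchy.soc_of(pt)


def _read_table(path: Path, delimiter: str, columns: tuple[str, ...]) -> tuple[pd.DataFrame, int]:
    bad: list[int] = []

    def _on_bad(line: list[str]) -> None:
        bad.append(1)
        return None

    frame = pd.read_csv(
        path,
        sep=delimiter,
        dtype=str,
        keep_default_na=False,
        engine="python",
        on_bad_lines=_on_bad,
    )
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path} lacks required columns {missing}")
    if bad:
        logger.warning("%s: %d malformed rows skipped", path, len(bad))
    return frame, len(bad)


def read_quarter(path: str | Path, dialect: FaersDialect = DEFAULT_DIALECT) -> RawQuarter:
    """Parse one quarterly extract directory into a :class:`RawQuarter`.

    Every table file is mandatory; a missing file raises ``FileNotFoundError``
    naming it.  Malformed rows are counted in ``RawQuarter.malformed`` rather
    than silently dropped.
    """
    path = Path(path)
    tables = {}
    malformed = {}
    specs = (
        ("DEMO", dialect.demo_pattern, DEMO_COLUMNS),
        ("DRUG", dialect.drug_pattern, DRUG_COLUMNS),
        ("REAC", dialect.reac_pattern, REAC_COLUMNS),
        ("OUTC", dialect.outc_pattern, OUTC_COLUMNS),
    )
    for name, pattern, columns in specs:
        matches = sorted(path.glob(pattern))
        if not matches:
            raise FileNotFoundError(f"mandatory {name} file matching {pattern!r} not found in {path}")
        frames = []
        n_bad = 0
        for f in matches:
            frame, bad = _read_table(f, dialect.delimiter, columns)
            frames.append(frame)
            n_bad += bad
        tables[name] = pd.concat(frames, ignore_index=True) if len(frames) > 1 else frames[0]
        malformed[name] = n_bad
    quarter = RawQuarter(
        demo_rows=tables["DEMO"],
        drug_rows=tables["DRUG"],
        reac_rows=tables["REAC"],
        outc_rows=tables["OUTC"],
        source=str(path),
        malformed=malformed,
    )
    quarter.validate()
    return quarter


def age_to_years(age: object, unit: object) -> float:
    """Convert an (age, unit) pair to years; unknown unit or blank age → NaN.

    A blank unit with an age present is read as years (the FAERS convention
    when the unit field is dropped)."""
    s = str(age).strip() if age is not None else ""
    if s == "" or s.lower() == "nan":
        return np.nan
    try:
        value = float(s)
    except ValueError:
        return np.nan
    if value < 0:
        return np.nan
    u = str(unit).strip().upper() if unit is not None else ""
    if u == "" or u == "NAN":
        return value
    factor = AGE_UNIT_YEARS.get(u)
    if factor is None:
        return np.nan
    return value * factor


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Keep one demography row per case id.

    The retained version is the one with the latest ``receipt_date`` (missing
    dates sort earliest); ties go to the largest ``caseversion``, then to the
    last file order (``file_order`` column if present, else input position).
    Idempotent and deterministic for a fixed input.
    """
    if demo.empty:
        return demo.copy()
    work = demo.copy()
    work["_pos"] = np.arange(len(work))
    added_file_order = "file_order" not in work.columns
    if added_file_order:
        work["file_order"] = 0
    work["_version"] = pd.to_numeric(work["caseversion"], errors="coerce").fillna(-1)
    work = work.sort_values(
        ["receipt_date", "_version", "file_order", "_pos"],
        na_position="first",
        kind="mergesort",
    )
    winners = work.groupby("caseid", sort=False).tail(1)
    winners = winners.sort_values("_pos", kind="mergesort")
    drop = ["_pos", "_version"] + (["file_order"] if added_file_order else [])
    return winners.drop(columns=drop).reset_index(drop=True)


def assemble_case_reports(
    quarters: Iterable[RawQuarter],
    dictionary: DrugDictionary,
    hierarchy: MedDRAHierarchy,
    *,
    unknown_pt: str = "error",
) -> ReportCorpus:
    """Join, normalise and deduplicate quarterly tables into a corpus.

    Deduplication is global across the full quarter span (FAERS resubmits
    cases across quarters).  Cases left with no mappable reaction are
    excluded and counted in ``corpus.log['cases_without_reactions']``.

    ``unknown_pt`` is ``"error"`` (raise on a PT absent from the hierarchy)
    or ``"bucket"`` (route it to the :data:`UNKNOWN_PT` event code).
    """
    quarters = list(quarters)
    if not quarters:
        raise ValueError("at least one quarter is required")
    if unknown_pt not in ("error", "bucket"):
        raise ValueError("unknown_pt must be 'error' or 'bucket'")

    demo = pd.concat(
        [q.demo_rows.assign(file_order=i) for i, q in enumerate(quarters)], ignore_index=True
    )
    demo["receipt_date"] = pd.to_datetime(demo["fda_dt"], format="%Y%m%d", errors="coerce")
    n_bad_dates = int((demo["receipt_date"].isna() & (demo["fda_dt"].str.strip() != "")).sum())

    winners = deduplicate(demo)
    keep_ids = set(winners["primaryid"])

    drug = pd.concat([q.drug_rows for q in quarters], ignore_index=True)
    reac = pd.concat([q.reac_rows for q in quarters], ignore_index=True)
    outc = pd.concat([q.outc_rows for q in quarters], ignore_index=True)
    drug = drug[drug["primaryid"].isin(keep_ids)]
    reac = reac[reac["primaryid"].isin(keep_ids)]
    outc = outc[outc["primaryid"].isin(keep_ids)]

    # drug normalisation
    concepts = drug["drugname"].map(dictionary.normalize)
    drugs = pd.DataFrame(
        {"case_id": drug["caseid"].values, "concept": concepts.values, "role": drug["role_cod"].str.strip().values}
    ).drop_duplicates(ignore_index=True)

    # PT mapping (REAC carries verbatim PT names)
    pt_codes = []
    soc_codes = []
    for name in reac["pt"]:
        try:
            code = hierarchy.pt_code_of(name)
            soc = hierarchy.soc_of(code)
        except UnknownPTError:
            if unknown_pt == "error":
                raise
            code, soc = UNKNOWN_PT, UNKNOWN_PT
        pt_codes.append(code)
        soc_codes.append(soc)
    reactions = pd.DataFrame(
        {"case_id": reac["caseid"].values, "pt_code": pt_codes, "soc_code": soc_codes}
    ).drop_duplicates(ignore_index=True)

    outcomes = pd.DataFrame(
        {"case_id": outc["caseid"].values, "outcome": outc["outc_cod"].str.strip().values}
    ).drop_duplicates(ignore_index=True)

    demo_out = pd.DataFrame(
        {
            "case_id": winners["caseid"].values,
            "receipt_date": winners["receipt_date"].values,
            "gender": winners["sex"].str.strip().map(lambda s: _GENDER_MAP.get(s, "unknown")).values,
            "age_years": [age_to_years(a, u) for a, u in zip(winners["age"], winners["age_cod"])],
            "country": winners["occr_country"].str.strip().mask(lambda s: s == "", np.nan).values,
        }
    )

    with_reactions = set(reactions["case_id"])
    no_reaction = ~demo_out["case_id"].isin(with_reactions)
    n_dropped = int(no_reaction.sum())
    if n_dropped:
        logger.info("excluded %d cases with no mappable reactions", n_dropped)
        kept_cases = set(demo_out.loc[~no_reaction, "case_id"])
        demo_out = demo_out[~no_reaction].reset_index(drop=True)
        drugs = drugs[drugs["case_id"].isin(kept_cases)].reset_index(drop=True)
        outcomes = outcomes[outcomes["case_id"].isin(kept_cases)].reset_index(drop=True)

    log = {
        "demo_rows_read": int(len(demo)),
        "unparseable_dates": n_bad_dates,
        "distinct_cases": int(len(winners)),
        "cases_without_reactions": n_dropped,
        "cases_assembled": int(len(demo_out)),
        "malformed_rows": {k: sum(q.malformed.get(k, 0) for q in quarters) for k in ("DEMO", "DRUG", "REAC", "OUTC")},
    }
    return ReportCorpus(demo=demo_out, drugs=drugs, reactions=reactions, outcomes=outcomes, log=log)
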