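"""Synthetic FAERS-style corpus generator with known ground truth.

Emulates the structure a disproportionality study actually consumes:
versioned case reports (duplicates), demographics with missingness, one or
more drug mentions per case with role codes, one or more MedDRA PT
reactions, serious-outcome codes, and — the part that makes statistical
tests meaningful — *implanted* drug–event pairs with a configurable true
reporting-rate ratio ρ.

Implantation semantics: for a case exposed to the implanted drug (any
mention, any role), the conditional probability of the implanted PT is
min(1, ρ·baseline); all other PTs are untouched, so the true reporting-rate
ratio equals ρ exactly whenever the cap does not bind.  Cases that sample
zero reactions are repaired by drawing a single fallback PT from the
baseline weights *excluding implanted PTs*, which keeps both arms of every
implanted pair exactly at their nominal probabilities.

Duplicates are value-identical to their base case except for a strictly
later receipt date and incremented version, so they exercise the dedup key
and nothing else.  A single ``numpy`` Generator seeded from the config
drives every draw; the same seed yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import descriptives
from .contingency import ROLE_ALL, build_table
from .faers_io import (
    DEMO_COLUMNS, DRUG_COLUMNS, OUTC_COLUMNS, REAC_COLUMNS,
    DEFAULT_DIALECT, DrugDictionary, FaersDialect, MedDRAHierarchy, ReportCorpus,
)


@dataclass(frozen=True)
class DrugSpec:
    """One drug in the catalog: concept id, verbatim spellings, exposure."""

    concept: str
    verbatims: tuple[str, ...]
    p_exposure: float
    role_probs: Mapping[str, float]


@dataclass(frozen=True)
class PTSpec:
    """One preferred term with its baseline per-case occurrence probability."""

    name: str
    p_baseline: float


@dataclass(frozen=True)
class ImplantedPair:
    """A (drug concept, PT name) pair with true reporting-rate ratio ρ."""

    concept: str
    pt_name: str
    rho: float


DEFAULT_DRUGS: tuple[DrugSpec, ...] = (
    DrugSpec("RX3008", ("CYCLOSPORINE", "CICLOSPORIN", "NEORAL", "SANDIMMUNE", "RESTASIS"),
             0.004, {"PS": 0.75, "SS": 0.15, "C": 0.10}),
    DrugSpec("RX42316", ("TACROLIMUS", "PROGRAF"), 0.15, {"PS": 0.40, "SS": 0.25, "C": 0.30, "I": 0.05}),
    DrugSpec("RX68149", ("MYCOPHENOLATE MOFETIL", "CELLCEPT"), 0.08, {"PS": 0.35, "SS": 0.30, "C": 0.35}),
    DrugSpec("RX8640", ("PREDNISONE", "DELTASONE"), 0.25, {"PS": 0.30, "SS": 0.25, "C": 0.45}),
    DrugSpec("RX6851", ("METHOTREXATE", "TREXALL"), 0.12, {"PS": 0.45, "SS": 0.20, "C": 0.35}),
    DrugSpec("RX1191", ("ASPIRIN", "ACETYLSALICYLIC ACID"), 0.18, {"PS": 0.20, "SS": 0.20, "C": 0.60}),
    DrugSpec("RX5640", ("IBUPROFEN", "ADVIL"), 0.12, {"PS": 0.30, "SS": 0.20, "C": 0.50}),
    DrugSpec("RX7646", ("OMEPRAZOLE", "PRILOSEC"), 0.15, {"PS": 0.15, "SS": 0.20, "C": 0.65}),
)

DEFAULT_PTS: tuple[PTSpec, ...] = (
    PTSpec("Headache", 0.18), PTSpec("Tremor", 0.05),
    PTSpec("Nausea", 0.12), PTSpec("Diarrhoea", 0.08), PTSpec("Vomiting", 0.04),
    PTSpec("Gingival hypertrophy", 0.01),
    PTSpec("Renal impairment", 0.06), PTSpec("Acute kidney injury", 0.02),
    PTSpec("Hypertension", 0.06),
    PTSpec("Pyrexia", 0.05), PTSpec("Drug ineffective", 0.25),
    PTSpec("Off label use", 0.15), PTSpec("Overdose", 0.02),
    PTSpec("Biliary anastomosis complication", 0.003),
    PTSpec("Rash", 0.04), PTSpec("Hirsutism", 0.01),
    PTSpec("Pneumonia", 0.03), PTSpec("Infection", 0.04),
    PTSpec("Hepatotoxicity", 0.015),
    PTSpec("Scleral hyperaemia", 0.01), PTSpec("Dry eye", 0.03), PTSpec("Eye irritation", 0.02),
    PTSpec("Punctal plug insertion", 0.002),
    PTSpec("Acute graft versus host disease", 0.005),
    PTSpec("Anaemia", 0.02), PTSpec("Thrombocytopenia", 0.01),
    PTSpec("Spermatozoa progressive motility decreased", 0.003),
    PTSpec("Blood creatinine increased", 0.03),
)

#: Age-band sampling (bounds inclusive, integer years) and their weights
#: conditional on a known age; weights echo a large immunosuppressant case
#: series (older-skewed, transplant-heavy population).
DEFAULT_AGE_BANDS: tuple[tuple[int, int], ...] = ((0, 19), (20, 39), (40, 59), (60, 79), (80, 99))
DEFAULT_AGE_BAND_PROBS: tuple[float, ...] = (0.137, 0.151, 0.295, 0.344, 0.073)

DEFAULT_COUNTRY_WEIGHTS: Mapping[str, float] = {
    "US": 0.50, "JP": 0.09, "CA": 0.06, "GB": 0.03, "FR": 0.02, "CN": 0.02,
    "DE": 0.08, "IT": 0.06, "BR": 0.06, "AU": 0.08,
}

DEFAULT_OUTCOME_PROBS: Mapping[str, float] = {
    "HO": 0.119, "DE": 0.097, "LT": 0.018, "DS": 0.008,
    "OT": 0.15, "CA": 0.002, "RI": 0.003,
}


@dataclass
class SyntheticConfig:
    """Generator parameters; the defaults are the package's study conditions."""

    n_cases: int = 10_000
    n_quarters: int = 8
    seed: int = 0
    drugs: tuple[DrugSpec, ...] = DEFAULT_DRUGS
    pts: tuple[PTSpec, ...] = DEFAULT_PTS
    implanted: tuple[ImplantedPair, ...] = ()
    duplicate_rate: float = 0.10
    p_gender_missing: float = 0.124
    p_female: float = 0.654          # conditional on a known gender
    p_age_missing: float = 0.5626
    age_band_probs: tuple[float, ...] = DEFAULT_AGE_BAND_PROBS
    p_country_missing: float = 0.10
    country_weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_COUNTRY_WEIGHTS))
    outcome_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_OUTCOME_PROBS))
    start_quarter: str = "2013Q1"

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.n_quarters < 1:
            raise ValueError("n_quarters must be >= 1")
        probs = [self.duplicate_rate, self.p_gender_missing, self.p_female,
                 self.p_age_missing, self.p_country_missing]
        probs += [d.p_exposure for d in self.drugs]
        probs += [p.p_baseline for p in self.pts]
        probs += list(self.outcome_probs.values())
        probs += list(self.age_band_probs)
        if any((not 0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.age_band_probs) - 1.0) > 1e-9:
            raise ValueError("age_band_probs must sum to 1")
        for d in self.drugs:
            if abs(sum(d.role_probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"role probabilities of {d.concept} must sum to 1")
        concepts = {d.concept for d in self.drugs}
        pt_names = {p.name for p in self.pts}
        for pair in self.implanted:
            if pair.rho < 0:
                raise ValueError("implanted rho must be >= 0")
            if pair.concept not in concepts:
                raise ValueError(f"implanted pair references unknown drug {pair.concept!r}")
            if pair.pt_name not in pt_names:
                raise ValueError(f"implanted pair references unknown PT {pair.pt_name!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drugs"] = [dataclasses.asdict(x) | {"role_probs": dict(x.role_probs)} for x in self.drugs]
        d["pts"] = [dataclasses.asdict(x) for x in self.pts]
        d["implanted"] = [dataclasses.asdict(x) for x in self.implanted]
        d["country_weights"] = dict(self.country_weights)
        d["outcome_probs"] = dict(self.outcome_probs)
        d["age_band_probs"] = list(self.age_band_probs)
        return d


@dataclass
class Truth:
    """Ground truth of one realisation, for closure and recovery tests."""

    n_cases: int
    final_versions: pd.Series          # case_id -> final version number
    pair_rho: dict                     # (concept, pt_name) -> true rho
    demo_rows_emitted: int
    gender_counts: dict
    age_band_counts: dict
    outcome_counts: dict


@dataclass
class _Realisation:
    corpus: ReportCorpus
    truth: Truth
    # raw emission arrays
    caseid: np.ndarray
    date1: np.ndarray       # datetime64[D] of version 1
    dup_rows: np.ndarray    # row indices with a second version
    date2: np.ndarray       # datetime64[D] aligned with dup_rows
    sex_raw: np.ndarray
    age_val: np.ndarray
    age_cod: np.ndarray
    country_raw: np.ndarray
    mention_case: np.ndarray    # row index per drug mention
    mention_concept: np.ndarray
    mention_role: np.ndarray
    mention_verbatim: np.ndarray
    react_case: np.ndarray      # row index per reaction
    react_pt_name: np.ndarray
    outc_case: np.ndarray
    outc_code: np.ndarray


def _style_name(name: str, style: int) -> str:
    if style == 1:
        return name.title()
    if style == 2:
        return name.lower()
    if style == 3:
        return name + "."
    return name


def _realise(cfg: SyntheticConfig, hierarchy: MedDRAHierarchy) -> _Realisation:
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cases
    caseid = np.char.add("1", np.char.zfill(np.arange(1, n + 1).astype(str), 7))

    # --- drug exposures -------------------------------------------------
    nd = len(cfg.drugs)
    p_drug = np.array([d.p_exposure for d in cfg.drugs])
    expo = rng.random((n, nd)) < p_drug
    none = ~expo.any(axis=1)
    if none.any():
        # every FAERS case names at least one drug
        fallback = rng.choice(nd, size=int(none.sum()), p=p_drug / p_drug.sum())
        expo[np.where(none)[0], fallback] = True
    roles = np.empty((n, nd), dtype=object)
    for j, spec in enumerate(cfg.drugs):
        codes = list(spec.role_probs)
        roles[:, j] = rng.choice(codes, size=n, p=[spec.role_probs[c] for c in codes])

    # --- reactions ------------------------------------------------------
    npt = len(cfg.pts)
    p_pt = np.array([p.p_baseline for p in cfg.pts])
    pt_index = {p.name: k for k, p in enumerate(cfg.pts)}
    drug_index = {d.concept: j for j, d in enumerate(cfg.drugs)}
    P = np.tile(p_pt, (n, 1))
    implanted_k = []
    for pair in cfg.implanted:
        j, k = drug_index[pair.concept], pt_index[pair.pt_name]
        P[expo[:, j], k] = min(1.0, pair.rho * p_pt[k])
        implanted_k.append(k)
    react = rng.random((n, npt)) < P
    empty = ~react.any(axis=1)
    if empty.any():
        fb = p_pt.copy()
        fb[implanted_k] = 0.0
        if fb.sum() == 0:
            fb = p_pt.copy()
        fb = fb / fb.sum()
        react[np.where(empty)[0], rng.choice(npt, size=int(empty.sum()), p=fb)] = True

    # --- demographics ---------------------------------------------------
    gender_missing = rng.random(n) < cfg.p_gender_missing
    female = rng.random(n) < cfg.p_female
    sex_raw = np.where(gender_missing, "", np.where(female, "F", "M"))

    age_missing = rng.random(n) < cfg.p_age_missing
    band = rng.choice(len(DEFAULT_AGE_BANDS), size=n, p=np.asarray(cfg.age_band_probs))
    lo = np.array([b[0] for b in DEFAULT_AGE_BANDS])[band]
    hi = np.array([b[1] for b in DEFAULT_AGE_BANDS])[band]
    age_int = lo + rng.integers(0, hi - lo + 1, size=n)
    extra_months = rng.integers(0, 12, size=n)
    use_months = age_int <= 1
    age_val = np.where(use_months, (age_int * 12 + extra_months).astype(str), age_int.astype(str))
    age_cod = np.where(use_months, "MON", "YR")
    age_val = np.where(age_missing, "", age_val)
    age_cod = np.where(age_missing, "", age_cod)

    country_missing = rng.random(n) < cfg.p_country_missing
    countries = list(cfg.country_weights)
    cw = np.array([cfg.country_weights[c] for c in countries], dtype=float)
    country_raw = np.asarray(rng.choice(countries, size=n, p=cw / cw.sum()), dtype=object)
    country_raw[country_missing] = ""

    # --- outcomes -------------------------------------------------------
    outc_codes = list(cfg.outcome_probs)
    outc_matrix = rng.random((n, len(outc_codes))) < np.array([cfg.outcome_probs[c] for c in outc_codes])

    # --- receipt dates and duplicate versions ---------------------------
    start = pd.Period(cfg.start_quarter, freq="Q").start_time
    end = (pd.Period(cfg.start_quarter, freq="Q") + (cfg.n_quarters - 1)).end_time
    span_days = (end.normalize() - start).days + 1
    date1 = (np.datetime64(start.date()) + rng.integers(0, span_days, size=n)).astype("datetime64[D]")
    n_dup = int(round(cfg.duplicate_rate * n))
    dup_rows = np.sort(rng.choice(n, size=n_dup, replace=False))
    date2 = date1[dup_rows] + rng.integers(30, 400, size=n_dup)

    # --- deduplicated truth corpus --------------------------------------
    final_date = date1.copy()
    final_date[dup_rows] = date2
    mi, mj = np.nonzero(expo)
    ri, rk = np.nonzero(react)
    oi, oj = np.nonzero(outc_matrix)
    concept_arr = np.array([d.concept for d in cfg.drugs], dtype=object)
    pt_name_arr = np.array([p.name for p in cfg.pts], dtype=object)
    pt_code_arr = np.array([hierarchy.pt_code_of(p.name) for p in cfg.pts], dtype=object)
    soc_code_arr = np.array([hierarchy.soc_of(c) for c in pt_code_arr], dtype=object)

    # mirror faers_io.age_to_years bit-for-bit (value * unit factor)
    age_years = np.where(
        age_val == "", np.nan,
        np.where(use_months, (age_int * 12 + extra_months).astype(float) * (1.0 / 12.0),
                 age_int.astype(float)),
    )
    demo = pd.DataFrame({
        "case_id": caseid,
        "receipt_date": pd.to_datetime(final_date),
        "gender": np.where(sex_raw == "F", "female", np.where(sex_raw == "M", "male", "unknown")),
        "age_years": age_years,
        "country": pd.Series(country_raw).replace("", np.nan).values,
    })
    drugs_long = pd.DataFrame({
        "case_id": caseid[mi], "concept": concept_arr[mj], "role": roles[mi, mj],
    })
    reactions_long = pd.DataFrame({
        "case_id": caseid[ri], "pt_code": pt_code_arr[rk], "soc_code": soc_code_arr[rk],
    })
    outcomes_long = pd.DataFrame({
        "case_id": caseid[oi], "outcome": np.array(outc_codes, dtype=object)[oj],
    })
    corpus = ReportCorpus(demo=demo, drugs=drugs_long, reactions=reactions_long,
                          outcomes=outcomes_long, log={"source": "synthetic", "seed": cfg.seed})

    versions = np.ones(n, dtype=int)
    versions[dup_rows] = 2
    summaries = descriptives.demographics_summary(corpus)
    outcome_counts = dict(zip(*(lambda t: (t.labels, t.counts))(descriptives.outcomes_summary(corpus))))
    truth = Truth(
        n_cases=n,
        final_versions=pd.Series(versions, index=caseid, name="final_version"),
        pair_rho={(p.concept, p.pt_name): p.rho for p in cfg.implanted},
        demo_rows_emitted=n + n_dup,
        gender_counts=dict(zip(summaries["gender"].labels, summaries["gender"].counts)),
        age_band_counts=dict(zip(summaries["age"].labels, summaries["age"].counts)),
        outcome_counts=outcome_counts,
    )

    # --- emission details (drawn last so the corpus is seed-stable even
    #     when files are never written) ---------------------------------
    verbatim = np.empty(len(mi), dtype=object)
    for j, spec in enumerate(cfg.drugs):
        rows = np.where(mj == j)[0]
        if rows.size == 0:
            continue
        picks = rng.choice(len(spec.verbatims), size=rows.size)
        styles = rng.choice(4, size=rows.size, p=[0.70, 0.15, 0.10, 0.05])
        verbatim[rows] = [_style_name(spec.verbatims[p], s) for p, s in zip(picks, styles)]

    return _Realisation(
        corpus=corpus, truth=truth,
        caseid=caseid, date1=date1, dup_rows=dup_rows, date2=date2,
        sex_raw=sex_raw, age_val=age_val, age_cod=age_cod, country_raw=np.asarray(country_raw, dtype=object),
        mention_case=mi, mention_concept=concept_arr[mj], mention_role=roles[mi, mj],
        mention_verbatim=verbatim,
        react_case=ri, react_pt_name=pt_name_arr[rk],
        outc_case=oi, outc_code=np.array(outc_codes, dtype=object)[oj],
    )


def simulate_corpus(cfg: SyntheticConfig, hierarchy: MedDRAHierarchy | None = None) -> tuple[ReportCorpus, Truth]:
    """Deduplicated ground-truth corpus for a config, without touching disk."""
    hierarchy = hierarchy or MedDRAHierarchy.default()
    r = _realise(cfg, hierarchy)
    return r.corpus, r.truth


def _quarter_label(period: pd.Period) -> str:
    return f"{period.year}Q{period.quarter}"


def generate(
    cfg: SyntheticConfig,
    outdir: str | Path,
    hierarchy: MedDRAHierarchy | None = None,
    dialect: FaersDialect = DEFAULT_DIALECT,
) -> tuple[list[Path], Truth]:
    """Write quarterly FAERS-dialect files plus ground-truth tables.

    Returns the list of quarter directories (chronological) and the
    :class:`Truth`.  Deterministic: the same config yields byte-identical
    files.  Duplicate case versions are emitted in the quarter of their own
    receipt date, so cross-quarter deduplication is exercised.
    """
    hierarchy = hierarchy or MedDRAHierarchy.default()
    r = _realise(cfg, hierarchy)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    start_p = pd.Period(cfg.start_quarter, freq="Q")
    periods = [start_p + i for i in range(cfg.n_quarters)]

    def quarter_of(dates: np.ndarray) -> np.ndarray:
        p = pd.PeriodIndex(pd.to_datetime(dates), freq="Q")
        idx = (p.year - start_p.year) * 4 + (p.quarter - start_p.quarter)
        return np.clip(idx, 0, cfg.n_quarters - 1)

    def fmt_dates(dates: np.ndarray) -> np.ndarray:
        return pd.to_datetime(dates).strftime("%Y%m%d").to_numpy()

    # one emission row set per (case, version)
    versions = [
        {"rows": np.arange(cfg.n_cases), "version": 1, "dates": r.date1},
        {"rows": r.dup_rows, "version": 2, "dates": r.date2},
    ]
    demo_parts, drug_parts, reac_parts, outc_parts = [], [], [], []
    mention_seq = np.concatenate([np.arange(1, c + 1) for c in np.bincount(r.mention_case, minlength=cfg.n_cases)]) \
        if r.mention_case.size else np.array([], dtype=int)
    for v in versions:
        rows, ver, dates = v["rows"], v["version"], v["dates"]
        if rows.size == 0:
            continue
        pid = np.char.add(r.caseid[rows].astype(str), str(ver))
        qidx = quarter_of(dates)
        demo_parts.append(pd.DataFrame({
            "primaryid": pid, "caseid": r.caseid[rows], "caseversion": ver,
            "fda_dt": fmt_dates(dates), "sex": r.sex_raw[rows],
            "age": r.age_val[rows], "age_cod": r.age_cod[rows],
            "occr_country": r.country_raw[rows], "_q": qidx,
        }))
        pid_by_row = dict(zip(rows.tolist(), pid.tolist()))
        q_by_row = dict(zip(rows.tolist(), qidx.tolist()))
        row_set = set(rows.tolist())
        sel = np.array([c in row_set for c in r.mention_case], dtype=bool)
        if sel.any():
            drug_parts.append(pd.DataFrame({
                "primaryid": [pid_by_row[c] for c in r.mention_case[sel]],
                "caseid": r.caseid[r.mention_case[sel]],
                "drug_seq": mention_seq[sel],
                "role_cod": r.mention_role[sel],
                "drugname": r.mention_verbatim[sel],
                "_q": [q_by_row[c] for c in r.mention_case[sel]],
            }))
        sel = np.array([c in row_set for c in r.react_case], dtype=bool)
        if sel.any():
            reac_parts.append(pd.DataFrame({
                "primaryid": [pid_by_row[c] for c in r.react_case[sel]],
                "caseid": r.caseid[r.react_case[sel]],
                "pt": r.react_pt_name[sel],
                "_q": [q_by_row[c] for c in r.react_case[sel]],
            }))
        sel = np.array([c in row_set for c in r.outc_case], dtype=bool)
        if sel.any():
            outc_parts.append(pd.DataFrame({
                "primaryid": [pid_by_row[c] for c in r.outc_case[sel]],
                "caseid": r.caseid[r.outc_case[sel]],
                "outc_cod": r.outc_code[sel],
                "_q": [q_by_row[c] for c in r.outc_case[sel]],
            }))

    tables = {
        "DEMO": (pd.concat(demo_parts, ignore_index=True), DEMO_COLUMNS),
        "DRUG": (pd.concat(drug_parts, ignore_index=True) if drug_parts else pd.DataFrame(columns=list(DRUG_COLUMNS) + ["_q"]), DRUG_COLUMNS),
        "REAC": (pd.concat(reac_parts, ignore_index=True) if reac_parts else pd.DataFrame(columns=list(REAC_COLUMNS) + ["_q"]), REAC_COLUMNS),
        "OUTC": (pd.concat(outc_parts, ignore_index=True) if outc_parts else pd.DataFrame(columns=list(OUTC_COLUMNS) + ["_q"]), OUTC_COLUMNS),
    }

    quarter_dirs = []
    for qi, period in enumerate(periods):
        qdir = outdir / _quarter_label(period)
        qdir.mkdir(parents=True, exist_ok=True)
        quarter_dirs.append(qdir)
        for name, (frame, columns) in tables.items():
            part = frame.loc[frame["_q"] == qi, list(columns)] if len(frame) else frame[list(columns)]
            part.to_csv(qdir / f"{name}.txt", sep=dialect.delimiter, index=False, lineterminator="\n")

    _write_truth(outdir, cfg, r.truth, hierarchy)
    return quarter_dirs, r.truth


def _write_truth(outdir: Path, cfg: SyntheticConfig, truth: Truth, hierarchy: MedDRAHierarchy) -> None:
    tdir = outdir / "truth"
    tdir.mkdir(exist_ok=True)
    truth.final_versions.rename_axis("case_id").reset_index().to_csv(tdir / "truth_cases.csv", index=False)
    pairs = pd.DataFrame(
        [{"concept": c, "pt_name": p, "pt_code": hierarchy.pt_code_of(p), "rho": rho}
         for (c, p), rho in truth.pair_rho.items()],
        columns=["concept", "pt_name", "pt_code", "rho"],
    )
    pairs.to_csv(tdir / "truth_pairs.csv", index=False)
    demo_rows = []
    for section, counts in (("gender", truth.gender_counts), ("age", truth.age_band_counts),
                            ("serious outcomes", truth.outcome_counts)):
        demo_rows += [{"section": section, "category": k, "count": v} for k, v in counts.items()]
    pd.DataFrame(demo_rows).to_csv(tdir / "truth_demographics.csv", index=False)
    manifest = {"config": cfg.to_dict(), "n_cases": truth.n_cases, "demo_rows_emitted": truth.demo_rows_emitted}
    (tdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))


def empirical_rr(
    corpus: ReportCorpus,
    drug: str,
    event: str,
    level: str = "PT",
    role_filter: Iterable[str] = ROLE_ALL,
) -> float:
    """Realised reporting-rate ratio [a/(a+b)]/[c/(c+d)] of a pair.

    The implantation acts on any mention of the drug, so the default
    exposure definition here is all roles.  Undefined (no exposed cases, or
    no event among comparators) → NaN.
    """
    t = build_table(corpus, drug, event, level=level, role_filter=role_filter)
    if (t.a + t.b) == 0 or t.c == 0 or (t.c + t.d) == 0:
        return float("nan")
    return (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
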