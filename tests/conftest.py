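from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from faerspv.faers_io import DrugDictionary, MedDRAHierarchy, ReportCorpus
from faerspv.synthetic_data import ImplantedPair, SyntheticConfig, simulate_corpus

settings.register_profile("suite", derandomize=True, max_examples=200, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def hierarchy() -> MedDRAHierarchy:
    return MedDRAHierarchy.default()


@pytest.fixture(scope="session")
def dictionary() -> DrugDictionary:
    return DrugDictionary.default()


@pytest.fixture(scope="session")
def small_corpus(hierarchy):
    """Small implanted synthetic corpus shared by oracle comparisons."""
    cfg = SyntheticConfig(
        n_cases=400, seed=7,
        implanted=(ImplantedPair("RX3008", "Hepatotoxicity", 5.0),),
    )
    corpus, truth = simulate_corpus(cfg, hierarchy)
    return corpus, truth


def corpus_from_cases(cases: list[dict], hierarchy: MedDRAHierarchy) -> ReportCorpus:
    """Build a tiny corpus from compact per-case dicts.

    Each dict: ``{"id", "drugs": [(concept, role), ...], "pts": [pt_name, ...],
    "outcomes": [...], "gender", "age", "country", "date"}`` (last five optional).
    """
    demo, drugs, reacs, outs = [], [], [], []
    for case in cases:
        cid = str(case["id"])
        demo.append({
            "case_id": cid,
            "receipt_date": pd.Timestamp(case.get("date", "2015-06-01")),
            "gender": case.get("gender", "unknown"),
            "age_years": case.get("age", np.nan),
            "country": case.get("country", np.nan),
        })
        for concept, role in case.get("drugs", []):
            drugs.append({"case_id": cid, "concept": concept, "role": role})
        for pt_name in case.get("pts", []):
            code = hierarchy.pt_code_of(pt_name)
            reacs.append({"case_id": cid, "pt_code": code, "soc_code": hierarchy.soc_of(code)})
        for oc in case.get("outcomes", []):
            outs.append({"case_id": cid, "outcome": oc})
    empty = {"drugs": ["case_id", "concept", "role"],
             "reacs": ["case_id", "pt_code", "soc_code"],
             "outs": ["case_id", "outcome"]}
    return ReportCorpus(
        demo=pd.DataFrame(demo),
        drugs=pd.DataFrame(drugs, columns=empty["drugs"] if not drugs else None),
        reactions=pd.DataFrame(reacs, columns=empty["reacs"] if not reacs else None),
        outcomes=pd.DataFrame(outs, columns=empty["outs"] if not outs else None),
    )


def write_quarter(path, demo=(), drug=(), reac=(), outc=(), delimiter="$"):
    """Write raw quarter files from row tuples (header always present)."""
    path.mkdir(parents=True, exist_ok=True)
    headers = {
        "DEMO": "primaryid$caseid$caseversion$fda_dt$sex$age$age_cod$occr_country",
        "DRUG": "primaryid$caseid$drug_seq$role_cod$drugname",
        "REAC": "primaryid$caseid$pt",
        "OUTC": "primaryid$caseid$outc_cod",
    }
    for name, rows in (("DEMO", demo), ("DRUG", drug), ("REAC", reac), ("OUTC", outc)):
        lines = [headers[name].replace("$", delimiter)]
        lines += [delimiter.join(str(v) for v in row) for row in rows]
        (path / f"{name}.txt").write_text("\n".join(lines) + "\n")
    return path
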