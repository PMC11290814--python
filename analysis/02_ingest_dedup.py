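#!/usr/bin/env python
"""Ingest the quarterly files, deduplicate case versions, assemble the corpus.

Reads the quarters written by 01_simulate.py, reports the cleaning funnel
(rows read → unparseable dates → distinct cases → cases without mappable
reactions → assembled), checks the distinct-case count against the
generator's truth file, and stores the assembled corpus as CSVs for the
descriptive and signal analyses.
"""

import argparse
from pathlib import Path

import pandas as pd

from faerspv.faers_io import DrugDictionary, MedDRAHierarchy, assemble_case_reports, read_quarter

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()

    indir = RESULTS / "synthetic_faers"
    quarter_dirs = sorted(p for p in indir.iterdir() if p.is_dir() and p.name != "truth")
    quarters = [read_quarter(p) for p in quarter_dirs]
    print(f"read {len(quarters)} quarters from {indir}")

    corpus = assemble_case_reports(quarters, DrugDictionary.default(), MedDRAHierarchy.default())
    print("cleaning funnel:")
    for key, value in corpus.log.items():
        print(f"  {key:<26}: {value}")

    truth = pd.read_csv(indir / "truth" / "truth_cases.csv", dtype={"case_id": str})
    assert corpus.n_cases == len(truth), "deduplicated case count disagrees with generator truth"
    print(f"distinct cases match generator truth: {corpus.n_cases}")

    outdir = RESULTS / "corpus"
    corpus.to_csv(outdir)
    print(f"assembled corpus stored under {outdir}")


if __name__ == "__main__":
    main()
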