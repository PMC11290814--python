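#!/usr/bin/env python
"""Demography and serious-outcome summary of the assembled corpus.

Produces the case-series characteristics table — gender, age bands,
top reporting countries, serious outcomes — with percentages of the total
event count, checks the gender/age/outcome counts against the generator's
truth file, and writes the table to results/tables/descriptives.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from faerspv.descriptives import demographics_summary, outcomes_summary, report_counts, summaries_to_frame
from faerspv.faers_io import ReportCorpus

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()

    corpus = ReportCorpus.from_csv(RESULTS / "corpus")
    demo = demographics_summary(corpus)
    outc = outcomes_summary(corpus)
    frame = summaries_to_frame(demo, outc, corpus.n_cases)

    truth = pd.read_csv(RESULTS / "synthetic_faers" / "truth" / "truth_demographics.csv")
    for section, table in (("gender", demo["gender"]), ("age", demo["age"])):
        want = dict(zip(truth.loc[truth["section"] == section, "category"],
                        truth.loc[truth["section"] == section, "count"]))
        got = dict(zip(table.labels, table.counts))
        assert got == want, f"{section} counts disagree with generator truth"
    print("gender and age-band counts match generator truth")

    counts = report_counts(corpus, drug="RX3008")
    print("corpus counts (case level vs pair level):")
    for key, value in counts.items():
        print(f"  {key:<22}: {value}")

    outdir = RESULTS / "tables"
    outdir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(outdir / "descriptives.csv", index=False)
    print(frame.to_string(index=False))


if __name__ == "__main__":
    main()
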