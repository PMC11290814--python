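#!/usr/bin/env python
"""Generate the study's synthetic FAERS-style corpus.

Writes 8 quarters of $-delimited DEMO/DRUG/REAC/OUTC files for 20,000 case
reports (10% duplicated as later case versions) with three adverse-event
signals implanted for the cyclosporine concept (RX3008):

* Hepatotoxicity, true reporting-rate ratio 8
* Scleral hyperaemia, true reporting-rate ratio 12
* Acute graft versus host disease, true reporting-rate ratio 6

Everything downstream (02–04) reads these files back through the ingest
layer, exactly as a real quarterly download would be processed.
"""

import argparse
from pathlib import Path

from faerspv.synthetic_data import ImplantedPair, SyntheticConfig, generate

RESULTS = Path(__file__).resolve().parent.parent / "results"

IMPLANTED = (
    ImplantedPair("RX3008", "Hepatotoxicity", 8.0),
    ImplantedPair("RX3008", "Scleral hyperaemia", 12.0),
    ImplantedPair("RX3008", "Acute graft versus host disease", 6.0),
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-cases", type=int, default=20_000)
    args = parser.parse_args()

    cfg = SyntheticConfig(n_cases=args.n_cases, n_quarters=8, seed=args.seed,
                          duplicate_rate=0.10, implanted=IMPLANTED)
    outdir = RESULTS / "synthetic_faers"
    quarter_dirs, truth = generate(cfg, outdir)

    print(f"wrote {len(quarter_dirs)} quarters under {outdir}")
    print(f"  case versions emitted : {truth.demo_rows_emitted}")
    print(f"  distinct cases (truth): {truth.n_cases}")
    print(f"  implanted pairs       : {truth.pair_rho}")


if __name__ == "__main__":
    main()
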