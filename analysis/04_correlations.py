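#!/usr/bin/env python
"""Coherence-fidelity correlations from the orientation scan.

Reads results/orientation_scan.csv (produced by 03_orientation_scan.py)
and fits Pearson correlations between the compass anisotropy Delta_S
and each coherence column, overall and stratified by the orientation
polar angle beta.

Writes results/correlations.json.
"""

import json
import os

from spincompass import correlation as corr
from spincompass.cli_io import read_results

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    table = read_results(os.path.join(RESULTS, "orientation_scan.csv"))
    x_cols = [
        c for c in table.columns
        if c not in ("alpha", "beta", "gamma", "delta_s", "gamma_s")
    ]
    report = {}
    for x in x_cols:
        overall, strata = corr.correlate_scan(
            table, x, "delta_s", beta_bin_edges=corr.default_beta_edges()
        )
        report[x] = {
            "overall": overall.as_dict(),
            "beta_strata": strata,
        }
        print(
            f"{x} vs delta_s: r={overall.r:+.4f} "
            f"(n={overall.n}, slope={overall.slope:.4g})"
        )
    out = os.path.join(RESULTS, "correlations.json")
    with open(out, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
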