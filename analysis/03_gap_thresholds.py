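"""Candidate delimitation thresholds and the coverage-optimal choice.

Reads the pipeline bundle written by step 02 and reports: the KDE
local-minima candidate thresholds of the pooled distance vector, how many
species each delimits, the optimum, the fixed 2.20% BIN comparison, and the
per-genus thresholds.
"""

import json

import pandas as pd

IN = "results/pipeline"


def main() -> None:
    report = json.load(open(f"{IN}/report.json"))
    print("candidate thresholds (%):",
          [round(c, 2) for c in report["candidates_pct"]])
    print("species delimited per candidate:", report["coverage"])
    print(f"optimum: {report['optimum_pct']:.2f}% delimits "
          f"{report['optimum_coverage']}/{report['n_species']} species")
    for t, c in report["fixed_evaluations"].items():
        print(f"fixed threshold {t}: delimits {c}/{report['n_species']}")
    genus = pd.read_csv(f"{IN}/genus.tsv", sep="\t")
    print("\nper-genus optimum thresholds:")
    print(genus.to_string(index=False))


if __name__ == "__main__":
    main()
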