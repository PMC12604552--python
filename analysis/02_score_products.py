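"""Nutri-Score letter distribution of the synthetic product list.

The products written by 01_simulate.py already carry scores (the generator
needs letters to allocate ledger value); this step reports the distribution
and the per-algorithm-class score summaries that the boxplot-style analysis
uses downstream.
"""

import pathlib

import pandas as pd

from nutriprocure import agreement

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    scored = pd.read_csv(OUT / "synthetic" / "products.csv")
    dist = (scored["nutri_letter"].value_counts(normalize=True) * 100).sort_index()
    print("Nutri-Score letter distribution (%):",
          {k: round(v, 1) for k, v in dist.items()})

    summary = agreement.points_distribution(scored)
    summary.to_csv(OUT / "points_distribution.csv", index=False)
    print("five-number score summaries by category x algorithm "
          f"({len(summary)} strata) -> results/points_distribution.csv")
    print(summary.round(1).to_string(index=False))


if __name__ == "__main__":
    main()
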