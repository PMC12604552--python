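"""Agreement between Nutri-Score letters and the guideline categories.

Two inputs are cross-tabulated:

* the published Viken County table (printed counts, n = 4,790), from which
  the overall disagreement (670 items, ~14%) and the per-group disagreement
  counts are recomputed, and
* the synthetic cohort, whose agreement structure is generated (not
  expert-judged) and therefore only needs to be qualitatively similar.

Writes results/crosstab_synthetic.csv and results/crosstab_published.csv.
"""

import pathlib

import pandas as pd

from nutriprocure import agreement

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def dump(tables: dict, path: pathlib.Path) -> None:
    frames = []
    for label, tab in tables.items():
        rep = tab.counts.copy()
        rep.insert(0, "band", rep.index)
        rep.insert(0, "food_group", label)
        frames.append(rep)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def main() -> None:
    published = agreement.load_published_crosstab()
    count, share = agreement.disagreement_summary(published["Overall"])
    print(f"published table: {count} products in disagreement ({share:.1f}%)")
    mix = agreement.category_mix(published["Overall"])
    print("published category mix (%):", {k: round(v, 1) for k, v in mix.items()})
    dump(published, OUT / "crosstab_published.csv")

    scored = pd.read_csv(OUT / "synthetic" / "products.csv")
    overall = agreement.build_cross_table(scored)
    by_group = agreement.build_cross_table(scored, group_by_food_group=True)
    summary = agreement.product_level_summary(scored)
    print(f"synthetic cohort: agreement {summary['agree_pct']:.1f}%, "
          f"disagreement {summary['disagree_pct']:.1f}% "
          f"(n = {summary['n']})")
    dump({"Overall": overall, **by_group}, OUT / "crosstab_synthetic.csv")


if __name__ == "__main__":
    main()
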