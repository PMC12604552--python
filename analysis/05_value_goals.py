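"""Per-school purchase-value shares, the share-vs-share regressions and the
procurement goal evaluation on the synthetic ledgers.

The A/B value share is regressed on the recommended-category value share
(the generator plants a slope of 0.94), and the unfavorable share (E, or
C-E for beverages) on the not-recommended share.  Schools are then checked
against both goal sets: the guideline-basis goal (>=70% recommended, <=8%
not recommended) and its Nutri-Score-basis counterpart (>=65% A/B, <=15%
unfavorable).

Writes results/school_shares.csv, results/regression_fits.json and
results/value_goals_scatter.png.
"""

import json
import pathlib

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from nutriprocure import goals, pipeline, simulate

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    purchases, _ = pipeline.read_purchases(OUT / "synthetic" / "ledger.csv")
    scored = pd.read_csv(OUT / "synthetic" / "products.csv")
    truth = json.loads((OUT / "synthetic" / "truth.json").read_text())

    shares = goals.value_shares(purchases, scored, simulate.guidance_map(truth))
    shares.to_csv(OUT / "school_shares.csv", index=False)

    fit_ab = goals.fit_share_regression(shares["share_recommended"],
                                        shares["share_ab"])
    fit_unf = goals.fit_share_regression(shares["share_not_recommended"],
                                         shares["share_unfavorable"])
    fits = {"ab_vs_recommended": fit_ab.__dict__,
            "unfavorable_vs_not_recommended": fit_unf.__dict__}
    (OUT / "regression_fits.json").write_text(json.dumps(fits, indent=2))
    print(f"A/B share vs recommended share: slope={fit_ab.slope:.2f} "
          f"(SE {fit_ab.stderr:.2f}, p={fit_ab.p_value:.1e}, n={fit_ab.n}); "
          f"planted slope {truth['config']['planted_slope']}")
    print(f"unfavorable vs not-recommended: slope={fit_unf.slope:.2f} "
          f"(p={fit_unf.p_value:.1e})")
    print("favorable goal translated through the fit: guideline 70% -> "
          f"Nutri-Score basis {goals.predict_favorable_goal(fit_ab, 70.0):.1f}%")

    for goal_set, name in ((goals.GUIDELINE_GOALS, "guideline 70/8"),
                           (goals.NUTRISCORE_GOALS, "Nutri-Score 65/15")):
        ev = goals.goal_evaluation(shares, goal_set)
        print(f"goal {name}: {int(ev['both_pass'].sum())}/{len(ev)} schools pass")

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, (xcol, ycol, fit) in zip(axes, [
            ("share_recommended", "share_ab", fit_ab),
            ("share_not_recommended", "share_unfavorable", fit_unf)]):
        guided = shares["received_guidance"]
        ax.scatter(shares.loc[guided, xcol], shares.loc[guided, ycol],
                   label="guided", c="tab:blue")
        ax.scatter(shares.loc[~guided, xcol], shares.loc[~guided, ycol],
                   label="unguided", facecolors="none", edgecolors="tab:blue")
        xs = shares[xcol].sort_values()
        ax.plot(xs, fit.intercept + fit.slope * xs, c="tab:blue", lw=1)
        ax.set_xlabel(xcol)
        ax.set_ylabel(ycol)
        ax.legend()
    fig.tight_layout()
    fig.savefig(OUT / "value_goals_scatter.png", dpi=120)
    print("-> results/school_shares.csv, regression_fits.json, "
          "value_goals_scatter.png")


if __name__ == "__main__":
    main()
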