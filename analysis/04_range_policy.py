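"""Apply the food-group-specific acceptable Nutri-Score ranges to the
synthetic cohort.

The default policy accepts A/B everywhere with role-based overrides (bread
toppings up to C, fish-based toppings and small-quantity ingredients up to
D, oil-based dressings any letter, juice up to C only in portions <=250 ml).

Writes results/procurement_advice.csv.
"""

import pathlib

import pandas as pd

from nutriprocure import policy

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    scored = pd.read_csv(OUT / "synthetic" / "products.csv")
    pol = policy.load_policy()
    advised = policy.advise_frame(scored, pol)
    advised.to_csv(OUT / "procurement_advice.csv", index=False)

    print("verdicts:", advised["verdict"].value_counts().to_dict())
    overrides = advised[advised["rule_id"] != "default"]
    print(f"{len(overrides)} products decided by override rules:",
          overrides["rule_id"].value_counts().to_dict())
    rescued = overrides[(overrides["verdict"] == "acceptable")
                        & ~overrides["nutri_letter"].isin(["A", "B"])]
    print(f"{len(rescued)} products with letter C-E accepted via overrides")


if __name__ == "__main__":
    main()
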