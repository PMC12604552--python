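"""Generate the synthetic study cohort: a ~4,800-product county procurement
list over 14 food groups and one quarter of purchase ledgers for 10 high
schools (5 of which received dietary guidance).

Writes results/synthetic/{products.csv, ledger.csv, truth.json}.
"""

import json
import pathlib

from nutriprocure import simulate

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 20260101


def main(seed: int = SEED) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = simulate.GeneratorConfig(seed=seed)
    scored, ledger, truth = simulate.simulate_study(cfg)
    scored.to_csv(OUT / "products.csv", index=False)
    ledger.to_csv(OUT / "ledger.csv", index=False)
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2))

    mix = scored["matvalget_category"].value_counts(normalize=True) * 100
    print(f"generated {len(scored)} products over "
          f"{scored['food_group'].nunique()} food groups")
    print("guideline category mix (%):",
          {k: round(v, 1) for k, v in mix.items()})
    print(f"ledger: {len(ledger)} purchase lines, "
          f"{ledger['value_nok'].sum():,.0f} NOK over "
          f"{ledger['school_id'].nunique()} schools")


if __name__ == "__main__":
    main()
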