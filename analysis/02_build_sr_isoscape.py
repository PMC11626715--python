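#!/usr/bin/env python
"""Step 2 — fit the ensemble strontium isoscape.

Selects predictors by forest permutation importance against permuted
decoys, fits the stacked ensemble (random forest, gradient boosting,
support vector, elastic net) with oblique-distance spatial covariates,
evaluates it by spatially blocked cross-validation against a lone
random forest, and writes the predicted isoscape (mean + per-pixel SD)
and the CV report under results/isoscape/.
"""

import json
from pathlib import Path

import pandas as pd

from isomigrate import eml
from isomigrate.grid import GEOGRAPHIC, GeoGrid, PredictorStack

SEED = 1
ROOT = Path(__file__).resolve().parent.parent / "results"
WORLD = ROOT / "world"
OUT = ROOT / "isoscape"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    training = pd.read_csv(WORLD / "training.csv")
    layers = {
        p.stem.removeprefix("predictor_"): GeoGrid.read_ascii(p, crs=GEOGRAPHIC)
        for p in sorted(WORLD.glob("predictor_*.asc"))
    }
    stack = PredictorStack(layers)

    selected = eml.select_predictors(training, stack, "auto", seed=SEED)
    print(f"predictor selection kept {len(selected)}/{len(stack)}: {selected}")

    model = eml.fit_ensemble(training, stack, selected=selected, seed=SEED)
    rf = eml.single_learner_cv(training, stack, "random_forest",
                               selected=selected, seed=SEED)
    iso = eml.build_isoscape(model, stack)
    iso.write(OUT / "sr_eml")

    report = {
        "selected_predictors": selected,
        "eml": model.cv_report.to_dict(),
        "rf_baseline": rf.to_dict(),
        "meta_weights": model.meta_weights,
        "meta_tvalues": model.meta_tvalues,
    }
    (OUT / "cv_report.json").write_text(json.dumps(report, indent=2) + "\n")

    print(f"EML spatial CV: RMSE={model.cv_report.rmse:.5f} "
          f"R2={model.cv_report.r2:.3f}")
    print(f"RF  spatial CV: RMSE={rf.rmse:.5f} R2={rf.r2:.3f}")
    best = max(model.meta_tvalues, key=lambda k: abs(model.meta_tvalues[k]))
    print(f"meta-learner is dominated by {best} "
          f"(|t| = {abs(model.meta_tvalues[best]):.1f})")


if __name__ == "__main__":
    main()
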