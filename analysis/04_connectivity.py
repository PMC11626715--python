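#!/usr/bin/env python
"""Step 4 — migratory connectivity and seasonal structure.

From the assignment metrics of the migrant specimens: the permutation
Mantel correlation between capture-site and origin-centroid distance
matrices (the migratory-connectivity statistic), centroid clustering of
specimens in (d2H, Sr) isotope space, and the seasonal trend of migrant
d2H against capture date.  Results go to results/connectivity.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from isomigrate import connectivity, synthetic

SEED = 1
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    metrics = pd.read_csv(ROOT / "assignment" / "metrics.csv",
                          dtype={"id": str})
    specimens = synthetic.read_specimens_csv(ROOT / "world" / "specimens.csv")
    migrants = metrics[~metrics.putative_local.astype(bool)].reset_index(drop=True)

    pair = connectivity.distance_matrices(migrants)
    mantel = connectivity.mantel_test(pair, n_perm=9999, seed=SEED)

    mig_spec = specimens[specimens.id.isin(migrants.id)]
    labels = connectivity.isotope_centroid_cluster(mig_spec, k="auto")
    trend = connectivity.seasonal_trend(mig_spec)

    out = {
        "n_migrants": int(len(migrants)),
        "mantel": {"r": mantel.r, "p": mantel.p, "n_perm": mantel.n_perm,
                   "alternative": mantel.alternative, "seed": mantel.seed},
        "isotope_clusters": {"k": int(labels.max()),
                             "sizes": np.bincount(labels)[1:].tolist()},
        "seasonal_trend": {"slope_permil_per_day": trend.slope,
                           "p": trend.p, "n": trend.n, "r2": trend.r2},
    }
    (ROOT / "connectivity.json").write_text(json.dumps(out, indent=2) + "\n")

    sig = "significant" if mantel.p < 0.05 else "not significant"
    print(f"Mantel connectivity over {len(migrants)} migrants: "
          f"r = {mantel.r:.2f}, p = {mantel.p:.4g} ({sig})")
    print(f"isotope centroid clustering chose k = {out['isotope_clusters']['k']} "
          f"groups of sizes {out['isotope_clusters']['sizes']}")
    print(f"seasonal d2H trend: {trend.slope:+.2f} permil/day "
          f"(p = {trend.p:.3g}, n = {trend.n}) — with a uniform capture "
          f"transect and common displacement no trend is expected here")


if __name__ == "__main__":
    main()
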