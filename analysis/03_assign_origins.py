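#!/usr/bin/env python
"""Step 3 — dual-isotope natal-origin assignment.

Assigns every specimen a posterior origin surface from the wing-d2H
isoscape and the fitted ensemble Sr isoscape, reduces each posterior to
its 2:1-odds highly probable region, screens putative locals (< 100 km),
and writes the per-specimen metrics, the stacked map, and a comparison
of dual-isotope vs d2H-only region areas under results/assignment/.
With the known true origins it also reports the empirical coverage of
the 2:1 region.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from isomigrate import assignment, synthetic
from isomigrate.grid import GEOGRAPHIC, Isoscape

ROOT = Path(__file__).resolve().parent.parent / "results"
WORLD = ROOT / "world"
OUT = ROOT / "assignment"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    specimens = synthetic.read_specimens_csv(WORLD / "specimens.csv")
    truth = pd.read_csv(WORLD / "truth.csv", dtype={"id": str})
    h_iso = Isoscape.read(WORLD / "h_isoscape", crs=GEOGRAPHIC)
    sr_iso = Isoscape.read(ROOT / "isoscape" / "sr_eml", crs=GEOGRAPHIC)

    dual, results = assignment.assign_table(specimens, h_iso, sr_iso)
    single, _ = assignment.assign_table(specimens, h_iso, None)
    dual.to_csv(OUT / "metrics.csv", index=False)
    assignment.stack_binaries([r.binary for r in results]).write_ascii(
        OUT / "stacked_all.asc")

    spec = h_iso.spec
    lookup = truth.set_index("id")
    hits = []
    for res in results:
        t = lookup.loc[res.specimen_id]
        hits.append(bool(res.binary.cells[spec.index_of(t.true_lon,
                                                        t.true_lat)]))
    n_local = int(dual.putative_local.sum())
    reduction = 100.0 * (1.0 - dual.area_km2.mean() / single.area_km2.mean())
    summary = {
        "n_specimens": int(len(dual)),
        "n_migrants": int(len(dual) - n_local),
        "n_putative_local": n_local,
        "coverage_of_true_origin_pct": 100.0 * float(np.mean(hits)),
        "mean_area_dual_km2": float(dual.area_km2.mean()),
        "mean_area_h_only_km2": float(single.area_km2.mean()),
        "area_reduction_pct": float(reduction),
        "mean_min_distance_km": float(
            dual.loc[~dual.putative_local, "min_distance_km"].mean()),
    }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    print(f"{summary['n_migrants']}/{summary['n_specimens']} specimens "
          f"classified as migrants (>100 km)")
    print(f"2:1 region contains the true origin for "
          f"{summary['coverage_of_true_origin_pct']:.1f}% of specimens "
          f"(nominal 66.7%; the fitted isoscape's conservative error "
          f"model over-covers)")
    print(f"adding Sr shrinks the highly probable area by "
          f"{reduction:.0f}% on average "
          f"({single.area_km2.mean() / 1e6:.2f} -> "
          f"{dual.area_km2.mean() / 1e6:.2f} Mkm2)")
    print(f"mean minimum migration distance of migrants: "
          f"{summary['mean_min_distance_km']:.0f} km")


if __name__ == "__main__":
    main()
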