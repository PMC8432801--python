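"""Simulate the study's survey data from a known latent abundance surface.

Generates the checklist stream (semi-structured, effort-heterogeneous,
hotspot-clustered, with filter-violating records injected) and the
route-stop stream (structured, 50 stops per route, one run per year) for a
community of species with alternating positive/negative log-linear trends,
plus the per-town attribute table.  Everything downstream is scored against
the latent surface written alongside.

Writes results/sim/: checklist_meta.csv, checklist_obs.csv, runs.csv,
stop_counts.csv, truth.csv, town_attributes.csv, scenario.json.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import numpy as np

from birdindex import pipeline, synthetic


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-species", type=int, default=6)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args(argv)

    sc = pipeline.Scenario(n_species=args.n_species)
    truth, checklists, stops = pipeline.simulate_scenario(sc, seed=args.seed)
    attrs = synthetic.make_town_attributes(truth, seed=args.seed + 99)

    args.out.mkdir(parents=True, exist_ok=True)
    checklists.write(args.out / "checklist_meta.csv", args.out / "checklist_obs.csv")
    stops.write(args.out / "runs.csv", args.out / "stop_counts.csv")
    truth.to_frame().to_csv(args.out / "truth.csv", index=False)
    attrs.to_csv(args.out / "town_attributes.csv", index=False)
    cfg = dataclasses.asdict(sc) | {"seed": args.seed,
                                    "species": truth.species,
                                    "trends": truth.trend.tolist()}
    (args.out / "scenario.json").write_text(json.dumps(cfg, indent=2) + "\n")

    per_year = checklists.meta.groupby("year").size()
    print(f"simulated {len(checklists.meta)} checklists over "
          f"{truth.years[0]}-{truth.years[-1]} "
          f"({per_year.min()}-{per_year.max()} per year), "
          f"{len(stops.runs)} route runs x {stops.stops_per_route} stops")
    print(f"{len(truth.species)} species, trends "
          f"{np.round(truth.trend, 2).tolist()}")
    print(f"wrote {args.out}/")


if __name__ == "__main__":
    main()
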