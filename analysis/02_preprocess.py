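"""Standardize both survey streams into per-species detection tables.

Applies the checklist effort filters (party size, duration, distance,
protocol, completeness, season, minimum list length), restricts each species
to its observed range, zero-fills presence/absence, and balances detections
against non-detections; expands route runs into per-stop detection and count
records with explicit zeros.

Writes results/prep/: filter_tally.json and, per species,
checklist_detections_<sp>.csv, stop_detections_<sp>.csv, stop_counts_<sp>.csv.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from birdindex import preprocess
from birdindex.synthetic import ChecklistTable, StopTable


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/prep"))
    args = ap.parse_args(argv)

    cfg = json.loads((args.sim / "scenario.json").read_text())
    checklists = ChecklistTable.read(args.sim / "checklist_meta.csv",
                                     args.sim / "checklist_obs.csv")
    stops = StopTable.read(args.sim / "runs.csv", args.sim / "stop_counts.csv",
                           cfg["stops_per_route"])

    filtered, tally = preprocess.filter_checklists(checklists)
    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "filter_tally.json").write_text(json.dumps(tally, indent=2) + "\n")
    print(f"filters kept {len(filtered.meta)}/{len(checklists.meta)} checklists; "
          f"rejections: {tally}")

    rng = np.random.default_rng(args.seed)
    for sp in cfg["species"]:
        ranged = preprocess.restrict_to_range(filtered, sp)
        det = preprocess.zero_fill(ranged, sp)
        bal = preprocess.balance_checklists(det, seed=int(rng.integers(2**31 - 1)))
        bal.to_csv(args.out / f"checklist_detections_{sp}.csv", index=False)

        ranged_stops = preprocess.restrict_stops_to_range(stops, sp)
        dp = preprocess.build_stop_detections(ranged_stops, sp, mode="detection")
        ra = preprocess.build_stop_detections(ranged_stops, sp, mode="count")
        dp.to_csv(args.out / f"stop_detections_{sp}.csv", index=False)
        ra.to_csv(args.out / f"stop_counts_{sp}.csv", index=False)
        print(f"{sp}: {len(det)} checklists in range "
              f"(detection rate {det['response'].mean():.2f}), "
              f"{len(bal)} after balancing "
              f"(rate {bal['response'].mean():.2f}); "
              f"{len(dp)} stop records (rate {dp['response'].mean():.3f})")
    print(f"wrote {args.out}/")


if __name__ == "__main__":
    main()
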