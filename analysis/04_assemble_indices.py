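"""Aggregate town estimates to state level and difference across years.

State annual estimates are inverse-SE-weighted means of town estimates with
propagated SEs; inter-annual change is the proportional change relative to
the previous year.

Writes results/index_series.csv (state series) and
results/interannual_changes.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from birdindex import indices


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--estimates", type=Path, default=Path("results/index_estimates.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args(argv)

    est = pd.read_csv(args.estimates)
    frames, report = indices.assemble_frame(est, scale="state")

    series_rows, change_rows = [], []
    for sp, frame in frames.items():
        for idx, s in frame.items():
            for yr, e, se in zip(s.years, s.estimates, s.ses):
                series_rows.append({"species_id": sp, "index_id": idx,
                                    "scale": "state", "year": int(yr),
                                    "estimate": e, "se": se})
            ch = indices.interannual_change(s)
            for yr, d in zip(ch.years, ch.changes):
                change_rows.append({"species_id": sp, "index_id": idx,
                                    "scale": "state", "year": int(yr),
                                    "change": d})
    pd.DataFrame(series_rows).to_csv(args.out / "index_series.csv", index=False)
    pd.DataFrame(change_rows).to_csv(args.out / "interannual_changes.csv", index=False)

    print(f"assembled {len(frames)} species x 4 indices at state level")
    if report["excluded"]:
        print(f"excluded (insufficient common years): {report['excluded']}")
    print(f"wrote {args.out}/index_series.csv and interannual_changes.csv")


if __name__ == "__main__":
    main()
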