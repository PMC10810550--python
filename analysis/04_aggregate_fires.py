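#!/usr/bin/env python
"""Aggregate a synthetic FIRMS hotspot file into the monthly modelling table.

Builds a two-year synthetic hotspot CSV (Kenya-like coordinates, 80%
presumed vegetation fires), keeps the vegetation fires, counts them per
calendar month with mean fire radiative power and brightness, joins a
synthetic monthly climate table, and prints the descriptive summary block
of the resulting modelling table.  Outputs land in results/aggregation/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from firefreq import firedata as fd

OUT = Path(__file__).resolve().parent.parent / "results" / "aggregation"
SEED = 76568


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    firms_path = OUT / "synthetic_firms_hotspots.csv"
    frame = fd.make_firms_fixture(5000, ("2017-01-01", "2018-12-31"), rng,
                                  path=firms_path)
    data = fd.read_firms_csv(firms_path)
    print(f"read {len(data)} hotspot records "
          f"({(frame['type'] == 0).mean():.0%} presumed vegetation fires)")

    monthly = fd.aggregate_monthly(data)  # default: vegetation fires only
    print(f"aggregated to {len(monthly)} months; "
          f"{monthly['fire_count'].sum()} vegetation-fire detections retained")

    climate = pd.DataFrame(
        {
            "year": monthly["year"],
            "month": monthly["month"],
            "rainfall": rng.uniform(10, 250, len(monthly)).round(2),
            "tmin": rng.uniform(12, 22, len(monthly)).round(2),
            "tmax": rng.uniform(24, 34, len(monthly)).round(2),
        }
    )
    climate.to_csv(OUT / "synthetic_climate.csv", index=False)

    table = fd.merge_climate(monthly, climate)
    table.to_csv(OUT / "modelling.csv", index=False)
    print(f"\nmodelling table ({len(table)} rows) -> {OUT / 'modelling.csv'}")
    print("\ndescriptive summary:")
    print(fd.summary_statistics(table).round(2).to_string(index=False))


if __name__ == "__main__":
    main()
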