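"""Segment raw fixes into foraging trips (300 m colony buffer, >1 h rule),
interpolate to the stage's fix interval and compute trip metrics."""

import pandas as pd

from _common import get_config, save_stage
from sitefidelity.pipeline import stage_segment


def main() -> None:
    cfg = get_config()
    out = stage_segment(cfg)
    save_stage(cfg, "segment", out)
    trips = pd.read_csv(cfg.outdir / "trips.csv")
    print(f"segmented {out['trips_segmented']} trips; "
          f"{out['excursions_below_min_duration']} excursions dropped "
          "(below minimum duration)")
    for stage, g in trips.groupby("stage"):
        print(f"  {stage}: {len(g)} trips, "
              f"mean duration {g['duration_hr'].mean():.1f} h, "
              f"mean max range {g['max_range_km'].mean():.1f} km")


if __name__ == "__main__":
    main()
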