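"""Compare trip-metric repeatability between bold and shy birds (84% CI
overlap rule) and fit the spatial-partitioning mixed models on foraging-site
coordinates."""

import pandas as pd

from _common import get_config, save_stage
from sitefidelity.pipeline import stage_repeatability, stage_spatial


def main() -> None:
    cfg = get_config()
    out = stage_repeatability(cfg)
    save_stage(cfg, "repeatability", out)
    tab = pd.read_csv(cfg.outdir / "repeatability.csv")
    for _, r in tab.iterrows():
        print(f"{r['stage']} {r['metric']:>9} {r['group']:>4}: "
              f"R = {r['R']:.3f} (84% CI {r['ci84_lo']:.3f}-{r['ci84_hi']:.3f})")
    for key, verdict in out["overlap_tests"].items():
        print(f"  bold vs shy, {key}: {verdict}")

    spatial = stage_spatial(cfg)
    save_stage(cfg, "spatial", spatial)
    for stage, models in spatial.items():
        for resp, m in models.items():
            p = m["lrt"]["boldness"]["p"]
            print(f"{stage} site {resp} ({m['transform']}): "
                  f"boldness LRT p = {p:.3f}")


if __name__ == "__main__":
    main()
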