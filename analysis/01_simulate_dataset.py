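"""Generate the synthetic tracking study: GPS fixes, novel-object tests,
colony table and ground truth, written under results/pipeline/data/."""

import pandas as pd

from _common import get_config, save_stage
from sitefidelity.pipeline import stage_simulate


def main() -> None:
    cfg = get_config()
    out = stage_simulate(cfg)
    save_stage(cfg, "simulate", out)
    fixes = pd.read_csv(cfg.datadir / "fixes.csv")
    tests = pd.read_csv(cfg.datadir / "personality.csv")
    print(f"simulated {out['n_birds']} birds at "
          f"{fixes['colony_id'].nunique()} colonies: "
          f"{len(fixes):,} GPS fixes, {len(tests)} novel-object tests")
    print(f"data written to {cfg.datadir}")


if __name__ == "__main__":
    main()
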