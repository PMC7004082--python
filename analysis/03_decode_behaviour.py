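"""Fit the 3-state step/turn HMM per breeding stage, decode behavioural
states with the Viterbi algorithm, and aggregate foraging runs into sites."""

import json

import pandas as pd

from _common import get_config, save_stage
from sitefidelity.pipeline import stage_decode, stage_hmm_fit, stage_sites


def main() -> None:
    cfg = get_config()
    save_stage(cfg, "hmm_fit", stage_hmm_fit(cfg))
    save_stage(cfg, "decode", stage_decode(cfg))
    out = stage_sites(cfg)
    save_stage(cfg, "sites", out)

    models = json.loads((cfg.outdir / "hmm.json").read_text())
    for stage, m in models.items():
        means = {m["labels"][str(i)]: round(v)
                 for i, v in enumerate(m["model"]["step_mean"])}
        print(f"{stage}: loglik {m['loglik']:.1f}, "
              f"state step means (m/fix) {means}")
    print(f"foraging sites: {out['n_sites']}; trips kept {out['trips_kept']}, "
          f"dropped for no area-restricted search {out['trips_no_ars']}")


if __name__ == "__main__":
    main()
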