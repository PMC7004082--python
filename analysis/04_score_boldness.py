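"""Score boldness from the novel-object tests (covariance PCA of the five
behaviour proportions), estimate its adjusted repeatability, and split birds
into bold and shy groups at the median."""

import pandas as pd

from _common import get_config, save_stage
from sitefidelity.pipeline import stage_personality


def main() -> None:
    cfg = get_config()
    out = stage_personality(cfg)
    save_stage(cfg, "personality", out)
    r = out["repeatability"]
    print(f"PC1 explains {out['pc1_variance_explained']:.1%} of test variance")
    print(f"adjusted repeatability R = {r['R']:.3f} "
          f"(95% CI {r['ci95'][0]:.3f}-{r['ci95'][1]:.3f}, p = {r['p']:.2g})")
    print(f"median split: {out['n_bold']} bold, {out['n_shy']} shy")


if __name__ == "__main__":
    main()
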