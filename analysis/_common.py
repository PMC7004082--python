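"""Shared plumbing for the numbered analysis scripts."""

import json
from pathlib import Path

from sitefidelity.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parent.parent


def get_config() -> PipelineConfig:
    cfg = PipelineConfig.from_yaml(ROOT / "analysis" / "config.yaml")
    cfg.workdir = str(ROOT / cfg.workdir)
    cfg.validate()
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    return cfg


def save_stage(cfg: PipelineConfig, name: str, out: dict) -> None:
    path = cfg.outdir / f"stage_{name}.json"
    path.write_text(json.dumps(out, indent=1, sort_keys=True, default=str))


def load_stage(cfg: PipelineConfig, name: str) -> dict:
    return json.loads((cfg.outdir / f"stage_{name}.json").read_text())
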