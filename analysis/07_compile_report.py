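"""Merge the per-stage outputs into report.json and check that the trip
bookkeeping reconciles (every segmented trip kept or dropped with a reason)."""

import json

from _common import get_config, load_stage


def main() -> None:
    cfg = get_config()
    stages = ["simulate", "segment", "hmm_fit", "decode", "sites",
              "personality", "fidelity", "repeatability", "spatial"]
    report = {"seed": cfg.seed,
              "stages": {s: load_stage(cfg, s) for s in stages}}
    seg = report["stages"]["segment"]
    sit = report["stages"]["sites"]
    report["counts"] = {
        "excursions_below_min_duration": seg["excursions_below_min_duration"],
        "trips_segmented": seg["trips_segmented"],
        "dropped_no_ars": sit["trips_no_ars"],
        "trips_kept": sit["trips_kept"],
    }
    assert report["counts"]["trips_segmented"] == \
        report["counts"]["trips_kept"] + report["counts"]["dropped_no_ars"], \
        "trip bookkeeping does not reconcile"
    (cfg.outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=str))
    print("trip bookkeeping reconciles:", report["counts"])
    print(f"report written to {cfg.outdir / 'report.json'}")


if __name__ == "__main__":
    main()
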