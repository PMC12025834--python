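"""End-to-end pipeline: config in, report directory out.

A pipeline config (JSON) provides either a synthetic-data spec or a signal
plus annotations, the comparison to run, and the constraint boxes (a named
preset, "search", or explicit bounds):

    {
      "synth": {"n_per_class": {"immature": 9, "background": 9},
                "durations": [5.0, 10.0],
                "gen": {"seed": 1}},
      "comparison": {"positive": "immature", "negative": "background"},
      "boxes": "preset_immature_vs_background",
      "preprocess": {"notch": false}
    }

or, for recorded data:

    {"signal": "rec.edf", "channel": "F1", "annotations": "annot.csv", ...}
"""

from __future__ import annotations

import json
from pathlib import Path

from . import io as _io
from . import presets as _presets
from .model import WaveTrainComparison
from .preprocess import FilterSpec
from .search import SearchConfig
from .synth import GenConfig, gen_dataset
from .types import ConstraintBox, Fragment
from .wavetrains import DetectionParams

__all__ = ["run_pipeline", "load_fragments", "resolve_boxes"]


def load_fragments(config: dict, seed: int | None = None) -> list[Fragment]:
    """Fragments from the synth spec or from signal + annotations."""
    if "synth" in config:
        spec = config["synth"]
        gen_kwargs = dict(spec.get("gen", {}))
        if seed is not None:
            gen_kwargs["seed"] = seed
        cfg = GenConfig(**gen_kwargs)
        durations = spec.get("durations", 8.0)
        if isinstance(durations, list):
            durations = tuple(durations)
        frags, _ = gen_dataset(spec["n_per_class"], durations, cfg)
        return frags
    if "signal" in config and "annotations" in config:
        rec = _io.read_signal(config["signal"])
        annot = _io.read_annotations(config["annotations"])
        return _io.cut_fragments(rec, annot, channel=config.get("channel", 0))
    raise ValueError("config must provide either 'synth' or 'signal'+'annotations'")


def resolve_boxes(spec):
    """Map a box spec to (red, blue) ConstraintBoxes or the string 'search'."""
    if spec == "search":
        return "search"
    if isinstance(spec, str):
        try:
            return getattr(_presets, spec)()
        except AttributeError as exc:
            raise ValueError(f"unknown preset {spec!r}") from exc
    if isinstance(spec, dict):
        red = ConstraintBox.from_dict(spec.get("red", {}))
        blue = ConstraintBox.from_dict(spec.get("blue", {}))
        return red, blue
    raise ValueError("boxes must be a preset name, 'search', or {red: .., blue: ..}")


def run_pipeline(config: dict | str, out_dir, seed: int | None = None) -> Path:
    """Execute preprocess -> CWT -> detection -> diagrams -> stats.

    Writes the wave-train table, diagram CSV/PNG pairs, histograms, scatter,
    a comparison JSON and a run manifest into *out_dir*; returns the path.
    """
    if isinstance(config, (str, Path)):
        config = _io.load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        fragments = load_fragments(config, seed=seed)
        comparison = config.get("comparison",
                                {"positive": "immature", "negative": "background"})
        pre_cfg = config.get("preprocess", {})
        filter_spec = FilterSpec(**{k: tuple(v) if isinstance(v, list) else v
                                    for k, v in pre_cfg.items() if k != "notch"})
        det_cfg = config.get("detection", {})
        model = WaveTrainComparison.from_fragments(
            fragments, comparison["positive"], comparison["negative"],
            filter_spec=filter_spec, notch=pre_cfg.get("notch", True),
            detection=DetectionParams(**det_cfg),
        )

        stage = "detect"
        group_a, group_b = model.detect()
        all_trains = [t for ft in group_a + group_b for t in ft.trains]
        _io.write_wavetrains(all_trains, out / "wave_trains.csv")

        stage = "boxes"
        boxes = resolve_boxes(config.get("boxes", "search"))
        search_cfg = SearchConfig(**{"seed": seed or 0, **config.get("search", {})})
        stage = "fit"
        if boxes == "search":
            results = model.fit(search=True, search_config=search_cfg)
        else:
            results = model.fit(red_box=boxes[0], blue_box=boxes[1])

        stage = "report"
        results.save_diagrams(out)
        results.save_histograms_and_scatter(out)
        payload = results.comparison.to_dict()
        payload["red_box"] = results.red_box.to_dict()
        payload["blue_box"] = results.blue_box.to_dict()
        payload["red_cell"] = list(results.red_cell)
        payload["blue_cell"] = list(results.blue_cell)
        payload["classification"] = results.classification
        with open(out / "comparison.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        with open(out / "summary.txt", "w") as fh:
            fh.write(results.summary() + "\n")
        _io.write_manifest(out, config if isinstance(config, dict) else {}, seed)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return out
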