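"""Presets, model/results surface, pipeline reports and CLI plumbing."""

import json
import math

import numpy as np
import pytest

from wtea import (ConstraintBox, preset_immature_vs_background,
                  preset_immature_vs_spindle, run_pipeline)
from wtea.model import midpoint_threshold_classification


class TestPresets:
    def test_immature_vs_background_bounds(self):
        red, blue = preset_immature_vs_background()
        assert red["max_psd"] == (50_000.0, None)
        assert blue["bandwidth"] == (2.0, None)
        for name in ("central_frequency", "duration_s", "duration_periods", "phase"):
            assert red[name] == (None, None)
            assert blue[name] == (None, None)
        assert red["bandwidth"] == (None, None)
        assert blue["max_psd"] == (None, None)

    def test_immature_vs_spindle_bounds(self):
        red, blue = preset_immature_vs_spindle()
        assert red["central_frequency"] == (None, 8.5)
        assert red["duration_periods"] == (1.6, None)
        assert red["bandwidth"] == (1.7, None)
        assert red["phase"] == (-math.pi, 1.5)
        assert blue["central_frequency"] == (None, 15.0)
        assert blue["bandwidth"] == (4.0, None)
        assert blue["phase"] == (-2.5, 2.5)
        assert red["max_psd"] == (None, None)
        assert blue["max_psd"] == (None, None)


class TestConstraintBox:
    def test_membership_inclusive(self, make_train):
        box = ConstraintBox(max_psd=(50_000.0, None))
        assert box.contains(make_train(max_psd=50_000.0))
        assert not box.contains(make_train(max_psd=49_999.9))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ConstraintBox(bandwidth=(5.0, 2.0))
        with pytest.raises(ValueError):
            ConstraintBox(phase=(-7.0, 0.0))
        with pytest.raises(KeyError):
            ConstraintBox(sharpness=(0, 1))

    def test_dict_round_trip(self):
        box = ConstraintBox(central_frequency=(None, 8.5), phase=(-2.5, 2.5))
        assert ConstraintBox.from_dict(box.to_dict()) == box


class TestMidpointClassification:
    def test_separated_groups_perfect(self):
        out = midpoint_threshold_classification([2.0, 3.0], [0.0, 0.5])
        assert out["sensitivity"] == 1.0 and out["specificity"] == 1.0
        assert 0.5 < out["threshold"] < 2.0

    def test_overlapping_groups_imperfect(self):
        out = midpoint_threshold_classification([1.0, 3.0], [2.0, 0.1])
        assert out["sensitivity"] < 1.0 or out["specificity"] < 1.0


class TestSearchedBoxes:
    def test_genetic_search_separates_groups_end_to_end(self, ivb_results):
        """GA-discovered boxes reach near-perfect separation on the data."""
        from wtea import SearchConfig
        model = ivb_results.model          # reuses cached detection
        res = model.fit(search=True,
                        search_config=SearchConfig(population=24, generations=12,
                                                   seed=2))
        assert res.auc_red >= 0.95
        assert res.auc_blue <= 0.05
        assert len(res.searches) == 2


class TestModelResults:
    def test_summary_mentions_key_quantities(self, ivb_results):
        text = ivb_results.summary()
        assert "AUC" in text and "sensitivity" in text and "Mann-Whitney" in text

    def test_auc_consistent_with_diagram_cells(self, ivb_results):
        res = ivb_results
        assert res.auc_red == res.diagram_red.cell(res.red_cell[0], res.red_cell[1])
        assert res.auc_blue == res.diagram_blue.cell(res.blue_cell[0], res.blue_cell[1])

    def test_rates_nonnegative(self, ivb_results):
        c = ivb_results.comparison
        for arr in (c.red_rates_a, c.red_rates_b, c.blue_rates_a, c.blue_rates_b):
            assert np.all(arr >= 0)


SMALL_CONFIG = {
    "synth": {"n_per_class": {"immature": 3, "background": 3},
              "durations": [4.0, 5.0], "gen": {"seed": 3}},
    "comparison": {"positive": "immature", "negative": "background"},
    "boxes": "preset_immature_vs_background",
    "preprocess": {"notch": False},
}


@pytest.fixture(scope="module")
def report_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("report")
    run_pipeline(SMALL_CONFIG, out, seed=3)
    return out


class TestPipeline:
    def test_report_contents(self, report_dir):
        for name in ("wave_trains.csv", "diagram_red.csv", "diagram_red.png",
                     "diagram_blue.csv", "comparison.json", "summary.txt",
                     "run_manifest.json", "hist_red.csv", "scatter.csv"):
            assert (report_dir / name).exists(), name

    def test_red_area_present_blue_absent_under_red_box(self, report_dir):
        """Under the PSD constraint the diagram keeps a red area only."""
        payload = json.loads((report_dir / "comparison.json").read_text())
        assert payload["auc"]["red"] >= 0.9
        from wtea.diagrams import read_diagram_csv
        diag = read_diagram_csv(report_dir / "diagram_red.csv")
        defined = diag.auc[~diag.mask]
        assert defined.min() >= 0.3   # no blue area under the red box

    def test_rerun_is_byte_identical(self, report_dir, tmp_path):
        run_pipeline(SMALL_CONFIG, tmp_path, seed=3)
        for name in ("wave_trains.csv", "diagram_red.csv", "comparison.json"):
            assert (tmp_path / name).read_bytes() == (report_dir / name).read_bytes()

    def test_config_without_inputs_rejected(self, tmp_path):
        with pytest.raises(RuntimeError, match="load"):
            run_pipeline({"comparison": {}}, tmp_path)


class TestCLI:
    def test_synth_writes_dataset(self, tmp_path):
        from click.testing import CliRunner
        from wtea.cli import main
        spec = tmp_path / "spec.json"
        spec.write_text(json.dumps({
            "n_per_class": {"background": 2, "spindle": 2}, "durations": 4.0}))
        out = tmp_path / "data"
        result = CliRunner().invoke(main, ["synth", "--config", str(spec),
                                           "--out", str(out), "--seed", "9"])
        assert result.exit_code == 0, result.output
        assert (out / "annotations.csv").exists()
        assert len(list(out.glob("*.csv"))) == 5   # 4 fragments + annotations

    def test_detect_and_diagram_commands(self, tmp_path):
        from click.testing import CliRunner
        from wtea import GenConfig, gen_dataset
        from wtea.io import write_annotations, write_signal_delimited
        import pandas as pd

        frags, table = gen_dataset({"immature": 2, "background": 2}, 4.0,
                                   GenConfig(seed=5))
        # concatenate into one recording with per-fragment annotations
        samples = np.concatenate([f.samples for f in frags])
        starts = np.cumsum([0] + [f.samples.size for f in frags[:-1]]) / 500.0
        table = pd.DataFrame({"id": [f.id for f in frags],
                              "label": [f.label for f in frags],
                              "start_s": starts,
                              "duration_s": [f.duration for f in frags]})
        sig = tmp_path / "rec.csv"
        write_signal_delimited(samples, sig, sampling_rate=500.0)
        annot = tmp_path / "annot.csv"
        write_annotations(table, annot)

        runner = CliRunner()
        wt = tmp_path / "trains.csv"
        r1 = runner.invoke(main_cli(), ["detect", str(sig), "--annotations", str(annot),
                                        "--out", str(wt), "--no-notch"])
        assert r1.exit_code == 0, r1.output
        r2 = runner.invoke(main_cli(), ["diagram", str(wt), "--annotations", str(annot),
                                        "--out", str(tmp_path / "diag")])
        assert r2.exit_code == 0, r2.output
        assert (tmp_path / "diag.csv").exists()


def main_cli():
    from wtea.cli import main
    return main
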