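"""Model/results interface tying the pipeline together.

:class:`WaveTrainComparison` is built from two groups of labeled EEG
fragments; ``fit()`` runs preprocessing, wavelet spectrograms, wave-train
detection and AUC-diagram construction, optionally searching for red/blue
constraint boxes, and returns a :class:`WaveTrainComparisonResults` with
the boxes, their diagram cells, per-fragment rates, group tests and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import stats as _stats_mod
from .cwt import cwt_spectrogram, default_freq_grid
from .diagrams import AUCDiagram, FragmentTrains, frequency_auc_diagram, fragment_rate
from .preprocess import FilterSpec, preprocess
from .search import SearchConfig, SearchResult, evolve
from .types import ConstraintBox, Fragment
from .wavetrains import DetectionParams, detect_wave_trains, median_power_floor

__all__ = ["WaveTrainComparison", "WaveTrainComparisonResults",
           "midpoint_threshold_classification"]


def midpoint_threshold_classification(pos_rates, neg_rates) -> dict:
    """Two-class rule at the midpoint between the groups' rate ranges.

    The threshold sits halfway between the smallest positive rate and the
    largest negative rate; sensitivity is the fraction of positives at or
    above it, specificity the fraction of negatives below it.
    """
    pos = np.asarray(pos_rates, dtype=float)
    neg = np.asarray(neg_rates, dtype=float)
    thr = (pos.min() + neg.max()) / 2.0
    return {
        "threshold": float(thr),
        "sensitivity": float(np.mean(pos >= thr)),
        "specificity": float(np.mean(neg < thr)),
    }


class WaveTrainComparison:
    """Two-group wave-train comparison model.

    Parameters
    ----------
    fragments_a, fragments_b : lists of Fragment
        Positive (first) and comparison group; AUC near 1 means more wave
        trains in the first group.
    filter_spec : FilterSpec
        Preconditioning filters; ``notch=False`` skips line-noise removal
        (synthetic data contains none).
    freqs : ndarray
        Analysis grid (default 0.1-50 Hz, 0.1 Hz step).
    detection : DetectionParams
        Candidate-maximum conditions.  When its ``floor`` is None the model
        uses ``floor_factor`` times the median spectrogram power pooled over
        *all* fragments, so between-group differences in absolute power are
        preserved.
    """

    def __init__(
        self,
        fragments_a: list[Fragment],
        fragments_b: list[Fragment],
        label_a: str | None = None,
        label_b: str | None = None,
        filter_spec: FilterSpec = FilterSpec(),
        notch: bool = False,
        freqs: np.ndarray | None = None,
        detection: DetectionParams = DetectionParams(),
    ):
        if not fragments_a or not fragments_b:
            raise ValueError("both groups must contain fragments")
        self.fragments_a = list(fragments_a)
        self.fragments_b = list(fragments_b)
        self.label_a = label_a or fragments_a[0].label
        self.label_b = label_b or fragments_b[0].label
        self.filter_spec = filter_spec
        self.notch = notch
        self.freqs = default_freq_grid() if freqs is None else np.asarray(freqs, float)
        self.detection = detection
        self._groups: tuple[list[FragmentTrains], list[FragmentTrains]] | None = None

    @classmethod
    def from_fragments(cls, fragments: list[Fragment], positive_label: str,
                       negative_label: str, **kwargs) -> "WaveTrainComparison":
        """Split a mixed fragment list by label into the two groups."""
        a = [f for f in fragments if f.label == positive_label]
        b = [f for f in fragments if f.label == negative_label]
        return cls(a, b, label_a=positive_label, label_b=negative_label, **kwargs)

    # ------------------------------------------------------------------
    def detect(self) -> tuple[list[FragmentTrains], list[FragmentTrains]]:
        """Preprocess, transform and detect wave trains for every fragment.

        Cached: repeated ``fit`` calls reuse the detection.
        """
        if self._groups is not None:
            return self._groups
        pre_a = [preprocess(f, self.filter_spec, notch=self.notch) for f in self.fragments_a]
        pre_b = [preprocess(f, self.filter_spec, notch=self.notch) for f in self.fragments_b]
        specs_a = [cwt_spectrogram(f, self.freqs) for f in pre_a]
        specs_b = [cwt_spectrogram(f, self.freqs) for f in pre_b]
        params = self.detection
        if params.floor is None:
            floor = median_power_floor(specs_a + specs_b, params.floor_factor)
            params = DetectionParams(
                floor=floor, floor_factor=params.floor_factor,
                overlap_dedupe=params.overlap_dedupe,
                overlap_threshold=params.overlap_threshold,
                include_truncated=params.include_truncated)
        group_a = [
            FragmentTrains(f.id, f.duration, detect_wave_trains(f, params, spec=s))
            for f, s in zip(pre_a, specs_a)
        ]
        group_b = [
            FragmentTrains(f.id, f.duration, detect_wave_trains(f, params, spec=s))
            for f, s in zip(pre_b, specs_b)
        ]
        self._groups = (group_a, group_b)
        return self._groups

    def fit(
        self,
        red_box: ConstraintBox | None = None,
        blue_box: ConstraintBox | None = None,
        search: bool = False,
        search_config: SearchConfig | None = None,
    ) -> "WaveTrainComparisonResults":
        """Evaluate (or search for) red and blue constraint boxes.

        With ``search=True`` a genetic search supplies any box not given
        explicitly; otherwise missing boxes stay unconstrained.
        """
        group_a, group_b = self.detect()
        base = search_config or SearchConfig()
        searches: dict[str, SearchResult] = {}
        if search and red_box is None:
            sc = SearchConfig(**{**base.__dict__, "direction": "red"})
            searches["red"] = evolve(group_a, group_b, sc)
            red_box = searches["red"].box
        if search and blue_box is None:
            sc = SearchConfig(**{**base.__dict__, "direction": "blue",
                                 "seed": base.seed + 1})
            searches["blue"] = evolve(group_a, group_b, sc)
            blue_box = searches["blue"].box
        red_box = red_box if red_box is not None else ConstraintBox()
        blue_box = blue_box if blue_box is not None else ConstraintBox()

        diagram_plain = frequency_auc_diagram(group_a, group_b, ConstraintBox(),
                                              grid=self.freqs)
        diagram_red = frequency_auc_diagram(group_a, group_b, red_box, grid=self.freqs)
        diagram_blue = frequency_auc_diagram(group_a, group_b, blue_box, grid=self.freqs)
        red_cell = diagram_red.best_cell("red")
        blue_cell = diagram_blue.best_cell("blue")

        def rates(group, box, cell):
            band = (cell[0], cell[1])
            return np.array([
                fragment_rate(ft.trains, box, band, ft.duration).rate for ft in group
            ])

        red_a = rates(group_a, red_box, red_cell)
        red_b = rates(group_b, red_box, red_cell)
        blue_a = rates(group_a, blue_box, blue_cell)
        blue_b = rates(group_b, blue_box, blue_cell)
        comparison = _stats_mod.compare_rates(
            self.label_a, self.label_b, red_a, red_b, blue_a, blue_b,
            fragment_ids_a=[ft.fragment_id for ft in group_a],
            fragment_ids_b=[ft.fragment_id for ft in group_b],
        )
        classification = midpoint_threshold_classification(red_a, red_b)
        return WaveTrainComparisonResults(
            model=self, red_box=red_box, blue_box=blue_box,
            diagram_unconstrained=diagram_plain,
            diagram_red=diagram_red, diagram_blue=diagram_blue,
            red_cell=red_cell, blue_cell=blue_cell,
            comparison=comparison, classification=classification,
            searches=searches,
        )


@dataclass
class WaveTrainComparisonResults:
    """Fitted comparison: boxes, diagrams, rates, tests, classification."""

    model: WaveTrainComparison
    red_box: ConstraintBox
    blue_box: ConstraintBox
    diagram_unconstrained: AUCDiagram
    diagram_red: AUCDiagram
    diagram_blue: AUCDiagram
    red_cell: tuple[float, float, float]
    blue_cell: tuple[float, float, float]
    comparison: "_stats_mod.GroupComparison"
    classification: dict
    searches: dict = field(default_factory=dict)

    @property
    def auc_red(self) -> float:
        return self.red_cell[2]

    @property
    def auc_blue(self) -> float:
        return self.blue_cell[2]

    def summary(self) -> str:
        c = self.comparison
        lines = [
            "Wave-train comparison results",
            "=" * 64,
            f"groups: {c.label_a} (positive, n={len(c.red_rates_a)}) vs "
            f"{c.label_b} (n={len(c.red_rates_b)})",
            f"red box:  {self.red_box}",
            f"  best cell [{self.red_cell[0]:.1f}, {self.red_cell[1]:.1f}] Hz, "
            f"AUC = {self.auc_red:.4g}, Mann-Whitney p = {c.mw_p_red:.4g}",
            f"blue box: {self.blue_box}",
            f"  best cell [{self.blue_cell[0]:.1f}, {self.blue_cell[1]:.1f}] Hz, "
            f"AUC = {self.auc_blue:.4g}, Mann-Whitney p = {c.mw_p_blue:.4g}",
            f"red-rate threshold {self.classification['threshold']:.3g}/s: "
            f"sensitivity = {self.classification['sensitivity']:.2%}, "
            f"specificity = {self.classification['specificity']:.2%}",
            f"Spearman blue-vs-red in {c.label_a}: rho = {c.spearman_a[0]:.3g} "
            f"(p = {c.spearman_a[1]:.3g})",
            f"Spearman blue-vs-red in {c.label_b}: rho = {c.spearman_b[0]:.3g} "
            f"(p = {c.spearman_b[1]:.3g})",
        ]
        return "\n".join(lines)

    # Convenience plotting/export hooks ---------------------------------
    def save_diagrams(self, out_dir) -> None:
        from pathlib import Path
        from .diagrams import render_diagram
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        render_diagram(self.diagram_unconstrained, str(out / "diagram_unconstrained"))
        render_diagram(self.diagram_red, str(out / "diagram_red"))
        render_diagram(self.diagram_blue, str(out / "diagram_blue"))

    def save_histograms_and_scatter(self, out_dir) -> None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _stats_mod.rate_histograms(self.comparison, "red",
                                   path_prefix=str(out / "hist_red"))
        _stats_mod.rate_histograms(self.comparison, "blue",
                                   path_prefix=str(out / "hist_blue"))
        _stats_mod.rate_scatter(self.comparison, path_prefix=str(out / "scatter"))
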