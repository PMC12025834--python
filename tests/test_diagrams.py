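"""AUC diagrams: rate counting, ROC/AUC, prefix-sum vs naive equality."""

import numpy as np
import pytest

from wtea import ConstraintBox, fragment_rate, frequency_auc_diagram, \
    characteristic_auc_diagram, render_diagram, roc_auc
from wtea.diagrams import FragmentTrains, read_diagram_csv


class TestFragmentRate:
    def test_band_counting(self, make_train):
        trains = [make_train(central_frequency=f) for f in (5.0, 9.0, 20.0)]
        fr = fragment_rate(trains, ConstraintBox(), (4.0, 10.0), duration=2.0)
        assert fr.rate == 1.0

    def test_psd_threshold_box(self, make_train):
        trains = [make_train(max_psd=40_000.0), make_train(max_psd=60_000.0)]
        box = ConstraintBox(max_psd=(50_000.0, None))
        fr = fragment_rate(trains, box, (0.1, 50.0), duration=1.0)
        assert fr.rate == 1.0

    def test_empty_trains_zero_rate(self):
        assert fragment_rate([], ConstraintBox(), (1.0, 2.0), 5.0).rate == 0.0

    def test_inclusive_band_edges(self, make_train):
        trains = [make_train(central_frequency=4.0), make_train(central_frequency=10.0)]
        assert fragment_rate(trains, ConstraintBox(), (4.0, 10.0), 1.0).rate == 2.0

    def test_invalid_band_rejected(self, make_train):
        with pytest.raises(ValueError):
            fragment_rate([make_train()], ConstraintBox(), (10.0, 4.0), 1.0)


class TestRocAuc:
    def test_complete_separation(self):
        assert roc_auc([4, 5, 6], [1, 2, 3]) == 1.0

    def test_identical_groups(self):
        assert roc_auc([1, 2, 3], [1, 2, 3]) == 0.5

    def test_brute_force_pairs(self):
        assert roc_auc([2, 4], [1, 3]) == 0.75

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [1.0])

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(7), rng.random(5)
        assert roc_auc(a, b) == pytest.approx(1.0 - roc_auc(b, a), abs=0)


def _groups_from_trains(trains_per_fragment, durations):
    return [FragmentTrains(f"f{i}", d, tr)
            for i, (tr, d) in enumerate(zip(trains_per_fragment, durations))]


def _naive_cell(group_a, group_b, box, lo, hi):
    ra = [fragment_rate(ft.trains, box, (lo, hi), ft.duration).rate for ft in group_a]
    rb = [fragment_rate(ft.trains, box, (lo, hi), ft.duration).rate for ft in group_b]
    return roc_auc(ra, rb)


class TestFrequencyDiagram:
    @pytest.fixture
    def groups(self, random_trains):
        rng = np.random.default_rng(5)
        a = _groups_from_trains(
            [random_trains(rng.integers(5, 30), rng, f"a{i}") for i in range(4)],
            rng.uniform(4, 9, 4))
        b = _groups_from_trains(
            [random_trains(rng.integers(5, 30), rng, f"b{i}") for i in range(5)],
            rng.uniform(4, 9, 5))
        return a, b

    def test_identical_groups_all_cells_half(self, groups):
        a, _ = groups
        diag = frequency_auc_diagram(a, a, grid=np.arange(1.0, 41.0, 1.0))
        defined = diag.auc[~diag.mask]
        assert np.all(defined == 0.5)

    def test_prefix_sums_match_naive_counting(self, groups):
        """Exact agreement with direct per-cell counting on random cells."""
        a, b = groups
        grid = np.arange(1.0, 41.0, 0.5)
        diag = frequency_auc_diagram(a, b, grid=grid)
        rng = np.random.default_rng(11)
        for _ in range(100):
            i, j = sorted(rng.integers(0, grid.size, 2))
            if i == j:
                continue
            naive = _naive_cell(a, b, ConstraintBox(), grid[i], grid[j])
            assert diag.auc[i, j] == naive

    def test_label_swap_antisymmetry(self, groups):
        a, b = groups
        grid = np.arange(1.0, 41.0, 1.0)
        ab = frequency_auc_diagram(a, b, grid=grid)
        ba = frequency_auc_diagram(b, a, grid=grid)
        keep = ~ab.mask
        # exact on the pair-count numerators; the final division can differ
        # by one rounding ulp
        assert np.max(np.abs(ab.auc[keep] + ba.auc[keep] - 1.0)) < 1e-12

    def test_same_distribution_mostly_neutral(self, random_trains):
        """Groups drawn from one distribution rarely show strong cells."""
        rng = np.random.default_rng(21)
        a = _groups_from_trains(
            [random_trains(40, rng, f"a{i}") for i in range(8)], [10.0] * 8)
        b = _groups_from_trains(
            [random_trains(40, rng, f"b{i}") for i in range(8)], [10.0] * 8)
        diag = frequency_auc_diagram(a, b, grid=np.arange(1.0, 41.0, 0.5))
        defined = diag.auc[~diag.mask]
        assert np.mean(np.abs(defined - 0.5) > 0.3) < 0.05

    def test_rates_monotone_in_band_inclusion(self, groups, make_train):
        a, _ = groups
        ft = a[0]
        rates = [fragment_rate(ft.trains, ConstraintBox(), (1.0, hi), ft.duration).rate
                 for hi in (5.0, 10.0, 20.0, 40.0)]
        assert all(r2 >= r1 for r1, r2 in zip(rates, rates[1:]))

    def test_empty_group_rejected(self, groups):
        with pytest.raises(ValueError):
            frequency_auc_diagram([], groups[1])


class TestCharacteristicDiagram:
    def test_identical_groups_half(self, random_trains):
        rng = np.random.default_rng(2)
        a = _groups_from_trains([random_trains(20, rng, f"a{i}") for i in range(3)],
                                [5.0] * 3)
        diag = characteristic_auc_diagram(a, a, ConstraintBox(), "max_psd", grid=50)
        assert np.all(diag.auc[~diag.mask] == 0.5)

    def test_planted_psd_shift_detected(self, random_trains, make_train):
        """Cells with lower bound above the planted PSD threshold go red."""
        rng = np.random.default_rng(3)
        p0 = 30_000.0
        a = []
        for i in range(5):
            trains = random_trains(15, rng, f"a{i}")
            trains += [make_train(max_psd=rng.uniform(2 * p0, 3 * p0),
                                  central_frequency=rng.uniform(5, 15),
                                  fragment_id=f"a{i}") for _ in range(8)]
            a.append(FragmentTrains(f"a{i}", 8.0, trains))
        b = _groups_from_trains([random_trains(15, rng, f"b{i}") for i in range(5)],
                                [8.0] * 5)
        grid = np.linspace(100.0, 3 * p0, 100)
        diag = characteristic_auc_diagram(a, b, ConstraintBox(), "max_psd", grid=grid)
        idx = np.where((grid >= 1.5 * p0) & (grid <= 2 * p0))[0]
        assert idx.size > 0
        assert np.all(diag.auc[idx, -1] >= 0.9)   # bands [lower, top of range]

    def test_matches_naive_counting(self, random_trains):
        rng = np.random.default_rng(4)
        a = _groups_from_trains([random_trains(20, rng, f"a{i}") for i in range(3)],
                                [5.0, 6.0, 7.0])
        b = _groups_from_trains([random_trains(20, rng, f"b{i}") for i in range(3)],
                                [5.0, 8.0, 9.0])
        grid = np.linspace(0.5, 5.0, 40)
        diag = characteristic_auc_diagram(a, b, ConstraintBox(), "duration_periods",
                                          grid=grid)
        cell_rng = np.random.default_rng(7)
        for _ in range(100):
            i, j = sorted(cell_rng.integers(0, 40, 2))
            if i == j:
                continue
            ra = [np.mean([grid[i] <= t.duration_periods <= grid[j]
                           for t in ft.trains]) * len(ft.trains) / ft.duration
                  for ft in a]
            rb = [np.mean([grid[i] <= t.duration_periods <= grid[j]
                           for t in ft.trains]) * len(ft.trains) / ft.duration
                  for ft in b]
            assert diag.auc[i, j] == roc_auc(ra, rb)

    def test_unknown_characteristic_rejected(self, random_trains):
        rng = np.random.default_rng(5)
        a = _groups_from_trains([random_trains(5, rng)], [5.0])
        with pytest.raises(ValueError):
            characteristic_auc_diagram(a, a, ConstraintBox(), "sharpness")


class TestRenderDiagram:
    def test_csv_round_trip_and_mask(self, tmp_path, random_trains):
        rng = np.random.default_rng(6)
        a = _groups_from_trains([random_trains(20, rng, f"a{i}") for i in range(3)],
                                [5.0] * 3)
        b = _groups_from_trains([random_trains(20, rng, f"b{i}") for i in range(3)],
                                [6.0] * 3)
        diag = frequency_auc_diagram(a, b, grid=np.arange(2.0, 30.0, 1.0))
        csv_path, png_path = render_diagram(diag, str(tmp_path / "diag"))
        back = read_diagram_csv(csv_path)
        keep = ~diag.mask
        assert np.array_equal(back.auc[keep], diag.auc[keep])
        # masked lower triangle is absent (NaN) in the CSV frame
        frame = diag.to_frame()
        assert np.isnan(frame.to_numpy().T[diag.mask]).all()
        assert (tmp_path / "diag.png").exists()

    def test_neutral_diagram_renders_without_saturated_pixels(self, tmp_path,
                                                              random_trains):
        import matplotlib.image as mpimg
        rng = np.random.default_rng(8)
        a = _groups_from_trains([random_trains(10, rng, f"a{i}") for i in range(3)],
                                [5.0] * 3)
        diag = frequency_auc_diagram(a, a, grid=np.arange(2.0, 30.0, 1.0))
        _, png_path = render_diagram(diag, str(tmp_path / "flat"))
        img = mpimg.imread(png_path)
        h, w = img.shape[:2]
        center = img[h // 3: 2 * h // 3, w // 3: 2 * w // 3, :3]
        saturated_red = (center[..., 0] > 0.9) & (center[..., 1] < 0.2) & (center[..., 2] < 0.2)
        saturated_blue = (center[..., 2] > 0.9) & (center[..., 1] < 0.2) & (center[..., 0] < 0.2)
        assert not saturated_red.any() and not saturated_blue.any()
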