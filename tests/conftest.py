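import numpy as np
import pytest

from wtea import (GenConfig, WaveTrainComparison, WaveTrain, gen_dataset,
                  preset_immature_vs_background, preset_immature_vs_spindle)


@pytest.fixture(scope="session")
def gen_cfg():
    return GenConfig(seed=1)


@pytest.fixture(scope="session")
def ivb_results():
    """Immature-vs-background comparison: 9 vs 9 fragments, preset boxes."""
    frags, _ = gen_dataset({"immature": 9, "background": 9}, (5.0, 10.0),
                           GenConfig(seed=1))
    model = WaveTrainComparison.from_fragments(frags, "immature", "background",
                                               notch=False)
    red, blue = preset_immature_vs_background()
    return model.fit(red_box=red, blue_box=blue)


@pytest.fixture(scope="session")
def ivs_results():
    """Immature-vs-spindle comparison: 6 vs 6 fragments, preset boxes."""
    frags, _ = gen_dataset({"immature": 6, "spindle": 6}, (5.0, 8.0),
                           GenConfig(seed=7))
    model = WaveTrainComparison.from_fragments(frags, "immature", "spindle",
                                               notch=False)
    red, blue = preset_immature_vs_spindle()
    return model.fit(red_box=red, blue_box=blue)


@pytest.fixture
def make_train():
    """Factory for wave trains with sensible defaults."""

    def _make(central_frequency=10.0, max_psd=1000.0, duration_s=0.3,
              bandwidth=2.0, phase=0.0, peak_time=1.0, fragment_id="f",
              truncated=False):
        return WaveTrain(
            peak_time=peak_time,
            central_frequency=central_frequency,
            max_psd=max_psd,
            duration_s=duration_s,
            duration_periods=duration_s * central_frequency,
            bandwidth=bandwidth,
            phase=phase,
            fragment_id=fragment_id,
            truncated=truncated,
        )

    return _make


@pytest.fixture
def random_trains(make_train):
    """Factory for a list of background-like trains with an RNG."""

    def _make(n, rng, fragment_id="f", psd_range=(100.0, 20_000.0),
              cf_range=(1.0, 40.0), bw_range=(0.5, 3.0), dp_range=(0.5, 5.0)):
        out = []
        for _ in range(n):
            cf = rng.uniform(*cf_range)
            dp = rng.uniform(*dp_range)
            out.append(make_train(
                central_frequency=cf,
                max_psd=rng.uniform(*psd_range),
                duration_s=dp / cf,
                bandwidth=rng.uniform(*bw_range),
                phase=rng.uniform(-np.pi, np.pi),
                peak_time=rng.uniform(0, 10),
                fragment_id=fragment_id,
            ))
        return out

    return _make
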