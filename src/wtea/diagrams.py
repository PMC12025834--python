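"""AUC diagrams: two-group differences in wave-train rates over band grids.

A frequency AUC diagram is an upper-triangular matrix whose cell
``(lo, hi)`` holds the ROC AUC of per-fragment wave-train rates counted in
the frequency band ``[lo, hi]`` (inclusive), with the first group as the
positive class: AUC near 1 means the first group has more wave trains in
that band, AUC near 0 fewer.  Characteristic diagrams are built the same
way over a grid of bounds on one of the six characteristics.

Per-fragment band counts are prefix differences of cumulative counts over
the grid, so every cell of the full 500 x 500 default grid is exact and the
whole diagram costs O(pairs x grid^2) simple comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CHARACTERISTICS, ConstraintBox

__all__ = [
    "FragmentTrains",
    "FragmentRate",
    "AUCDiagram",
    "fragment_rate",
    "roc_auc",
    "frequency_auc_diagram",
    "characteristic_auc_diagram",
    "render_diagram",
    "read_diagram_csv",
]


@dataclass
class FragmentTrains:
    """Wave trains of one fragment plus what rate normalization needs."""

    fragment_id: str
    duration: float
    trains: list

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("fragment duration must be positive")


@dataclass(frozen=True)
class FragmentRate:
    """Wave trains per second within a box and band, for one fragment."""

    fragment_id: str
    group: str
    rate: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be nonnegative")


def fragment_rate(trains: list, box: ConstraintBox, band: tuple[float, float],
                  duration: float, fragment_id: str = "", group: str = "") -> FragmentRate:
    """Rate of trains satisfying *box* with central frequency in *band*.

    Band membership is inclusive on both ends; the rate divides by the
    annotated fragment duration.
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError("band lower limit must be below the upper limit")
    if duration <= 0:
        raise ValueError("duration must be positive")
    count = sum(
        1 for t in trains
        if lo <= t.central_frequency <= hi and box.contains(t)
    )
    return FragmentRate(fragment_id=fragment_id, group=group, rate=count / duration)


def roc_auc(positive_rates, negative_rates) -> float:
    """Mann-Whitney AUC with half credit for ties; positive class first.

    AUC = (1/nm) * sum_ij [pos_i > neg_j] + 0.5 [pos_i == neg_j].
    """
    pos = np.asarray(positive_rates, dtype=float)
    neg = np.asarray(negative_rates, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be nonempty")
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return float((gt + 0.5 * eq) / (pos.size * neg.size))


@dataclass
class AUCDiagram:
    """Upper-triangular AUC matrix over (lower limit, upper limit) cells.

    ``auc[i, j]`` is the AUC for the band ``[grid[i], grid[j]]``; cells with
    ``i >= j`` are undefined and masked.  ``kind`` is "frequency" or the
    characteristic name the grid bounds refer to.
    """

    auc: np.ndarray
    grid: np.ndarray
    kind: str = "frequency"
    mask: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = self.grid.size
        if self.auc.shape != (n, n):
            raise ValueError("auc matrix shape inconsistent with grid")
        if self.mask is None:
            self.mask = ~np.triu(np.ones((n, n), dtype=bool), k=1)
        defined = self.auc[~self.mask]
        if defined.size and (defined.min() < -1e-12 or defined.max() > 1 + 1e-12):
            raise ValueError("AUC values must lie in [0, 1]")

    def cell(self, lo: float, hi: float) -> float:
        i = int(np.argmin(np.abs(self.grid - lo)))
        j = int(np.argmin(np.abs(self.grid - hi)))
        if i >= j:
            raise ValueError("cell requires lower < upper")
        return float(self.auc[i, j])

    def best_cell(self, direction: str = "red") -> tuple[float, float, float]:
        """(lower, upper, auc) of the extreme cell.

        direction "red" returns the maximum-AUC cell (more trains in the
        first group), "blue" the minimum.
        """
        vals = np.where(self.mask, np.nan, self.auc)
        if direction == "red":
            flat = np.nanargmax(vals)
        elif direction == "blue":
            flat = np.nanargmin(vals)
        else:
            raise ValueError("direction must be 'red' or 'blue'")
        i, j = np.unravel_index(flat, vals.shape)
        return float(self.grid[i]), float(self.grid[j]), float(self.auc[i, j])

    def to_frame(self) -> pd.DataFrame:
        """Rows = upper limit, columns = lower limit; masked cells NaN."""
        vals = np.where(self.mask, np.nan, self.auc)
        return pd.DataFrame(vals.T, index=self.grid, columns=self.grid)


def _values_in_box(group: list[FragmentTrains], box: ConstraintBox,
                   characteristic: str) -> list[np.ndarray]:
    """Per fragment, the chosen characteristic of trains passing the box."""
    out = []
    for ft in group:
        vals = [t.characteristic(characteristic) for t in ft.trains if box.contains(t)]
        out.append(np.sort(np.asarray(vals, dtype=float)))
    return out


def _cumulative_counts(sorted_vals: np.ndarray, grid: np.ndarray):
    """(#values < g, #values <= g) for every grid point g."""
    lt = np.searchsorted(sorted_vals, grid, side="left").astype(float)
    le = np.searchsorted(sorted_vals, grid, side="right").astype(float)
    return lt, le


def _auc_matrix(vals_a: list[np.ndarray], durs_a: np.ndarray,
                vals_b: list[np.ndarray], durs_b: np.ndarray,
                grid: np.ndarray) -> np.ndarray:
    """AUC per (lower, upper) cell via the prefix-difference identity.

    For a pair of fragments (a, b), the comparison of rates in band [g_i,
    g_j] reduces to comparing ``u_le[j] - u_lt[i]`` with 0, where
    ``u = d_b * cum_a - d_a * cum_b``; the cell matrix of one pair is an
    outer comparison of two vectors, so ties and signs are exact.
    """
    n = grid.size
    cums_a = [_cumulative_counts(v, grid) for v in vals_a]
    cums_b = [_cumulative_counts(v, grid) for v in vals_b]
    acc = np.zeros((n, n))
    for (lt_a, le_a), da in zip(cums_a, durs_a):
        for (lt_b, le_b), db in zip(cums_b, durs_b):
            u_le = db * le_a - da * le_b
            u_lt = db * lt_a - da * lt_b
            diff = u_le[None, :] - u_lt[:, None]   # rows i (lower), cols j (upper)
            acc += (diff > 0) + 0.5 * (diff == 0)
    return acc / (len(vals_a) * len(vals_b))


def _build_diagram(group_a, group_b, box, characteristic, grid, kind) -> AUCDiagram:
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    vals_a = _values_in_box(group_a, box, characteristic)
    vals_b = _values_in_box(group_b, box, characteristic)
    durs_a = np.array([ft.duration for ft in group_a])
    durs_b = np.array([ft.duration for ft in group_b])
    auc = _auc_matrix(vals_a, durs_a, vals_b, durs_b, grid)
    n = grid.size
    mask = ~np.triu(np.ones((n, n), dtype=bool), k=1)
    auc = np.where(mask, 0.5, auc)
    return AUCDiagram(auc=auc, grid=grid, kind=kind)


def frequency_auc_diagram(
    group_a: list[FragmentTrains],
    group_b: list[FragmentTrains],
    box: ConstraintBox = ConstraintBox(),
    grid: np.ndarray | None = None,
) -> AUCDiagram:
    """Frequency AUC diagram of group A (positive) vs group B under *box*."""
    if grid is None:
        from .cwt import default_freq_grid
        grid = default_freq_grid()
    grid = np.asarray(grid, dtype=float)
    return _build_diagram(group_a, group_b, box, "central_frequency", grid, "frequency")


def characteristic_auc_diagram(
    group_a: list[FragmentTrains],
    group_b: list[FragmentTrains],
    box: ConstraintBox,
    characteristic: str,
    grid: np.ndarray | int = 100,
) -> AUCDiagram:
    """AUC diagram over [lower, upper] bounds of one characteristic.

    Any frequency-band constraint should be folded into *box* as
    central_frequency bounds.  An integer *grid* requests that many uniform
    bins spanning the pooled observed range of the characteristic.
    """
    if characteristic not in CHARACTERISTICS:
        raise ValueError(f"unknown characteristic {characteristic!r}")
    if isinstance(grid, (int, np.integer)):
        pooled = np.concatenate(
            _values_in_box(group_a, box, characteristic)
            + _values_in_box(group_b, box, characteristic)
        ) if (group_a or group_b) else np.array([])
        if pooled.size == 0:
            raise ValueError("no wave trains inside the box to span a grid")
        lo, hi = float(pooled.min()), float(pooled.max())
        if hi <= lo:
            hi = lo + 1.0
        grid = np.linspace(lo, hi, int(grid))
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    return _build_diagram(group_a, group_b, box, characteristic, grid, characteristic)


def render_diagram(diagram: AUCDiagram, path_prefix: str) -> tuple[str, str]:
    """Write the diagram as CSV matrix and raster image.

    CSV rows are band upper limits, columns lower limits, masked cells
    empty.  The image uses a jet-like colormap with AUC 0 blue, 0.5
    neutral, 1 red.  Returns (csv_path, png_path).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    csv_path = f"{path_prefix}.csv"
    png_path = f"{path_prefix}.png"
    frame = diagram.to_frame()
    frame.to_csv(csv_path, index_label="upper\\lower")

    fig, ax = plt.subplots(figsize=(6, 5))
    vals = np.where(diagram.mask, np.nan, diagram.auc)
    g = diagram.grid
    im = ax.pcolormesh(g, g, vals.T, cmap="jet", vmin=0.0, vmax=1.0, shading="nearest")
    ax.set_xlabel(f"band lower limit ({'Hz' if diagram.kind == 'frequency' else diagram.kind})")
    ax.set_ylabel("band upper limit")
    fig.colorbar(im, ax=ax, label="AUC")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return csv_path, png_path


def read_diagram_csv(csv_path: str, kind: str = "frequency") -> AUCDiagram:
    """Round-trip reader for :func:`render_diagram` CSV output."""
    frame = pd.read_csv(csv_path, index_col=0, float_precision="round_trip")
    grid = frame.index.to_numpy(dtype=float)
    auc = frame.to_numpy(dtype=float).T
    n = grid.size
    mask = ~np.triu(np.ones((n, n), dtype=bool), k=1)
    auc = np.where(mask, 0.5, auc)
    return AUCDiagram(auc=auc, grid=grid, kind=kind, mask=mask)
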