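"""Statistical layer: Mann-Whitney tests, Spearman correlation, histograms.

Two-sided p-values throughout.  The Mann-Whitney U statistic is tied to the
diagram AUC by the identity AUC = U / (n*m) (half credit for ties on both
sides).  No multiple-testing correction is applied across diagram cells;
constraint boxes are selected and tested on the same fragments unless the
caller splits them, and reports should state as much.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .diagrams import roc_auc

__all__ = ["mann_whitney", "spearman", "GroupComparison", "compare_rates",
           "rate_histograms", "rate_scatter", "overlap_coefficient"]

#: Sample-size ceiling for the exact (enumeration) Mann-Whitney p-value.
EXACT_MW_LIMIT = 20
#: Sample-size ceiling for the exact permutation Spearman p-value.
EXACT_SPEARMAN_LIMIT = 9


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U (of the first sample) and two-sided p.

    Exact enumeration when n+m <= 20 with no ties, otherwise the normal
    approximation with tie and continuity corrections.  U/(n*m) equals
    :func:`wtea.diagrams.roc_auc` of the two samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= EXACT_MW_LIMIT and not has_ties) else "asymptotic"
    res = _stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                              use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _midranks(x: np.ndarray) -> np.ndarray:
    return _stats.rankdata(x, method="average")


@lru_cache(maxsize=8)
def _rank_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int64)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p.

    rho is the Pearson correlation of mid-ranks.  For n <= 9 the p-value is
    an exact permutation probability (all n! orderings of one variable,
    valid with ties); larger samples use the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx = _midranks(x)
    ry = _midranks(y)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = np.sqrt((sx ** 2).sum() * (sy ** 2).sum())
    if denom == 0:
        return float("nan"), 1.0
    rho = float((sx * sy).sum() / denom)

    if n <= EXACT_SPEARMAN_LIMIT:
        perms = _rank_permutations(n)
        sy_perm = sy[perms]                       # (n!, n)
        rho_perm = (sy_perm @ sx) / denom
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    else:
        # t approximation on n-2 degrees of freedom
        t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho ** 2))
        p = float(2 * _stats.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0)


@dataclass
class GroupComparison:
    """Red/blue rate comparison between two fragment groups.

    Rates are wave trains per second inside the red/blue constraint boxes
    (and their diagram bands); Spearman correlations relate blue to red
    rates within each group.
    """

    label_a: str
    label_b: str
    red_rates_a: np.ndarray
    red_rates_b: np.ndarray
    blue_rates_a: np.ndarray
    blue_rates_b: np.ndarray
    fragment_ids_a: list[str] = field(default_factory=list)
    fragment_ids_b: list[str] = field(default_factory=list)
    auc_red: float = float("nan")
    auc_blue: float = float("nan")
    mw_p_red: float = float("nan")
    mw_p_blue: float = float("nan")
    spearman_a: tuple[float, float] = (float("nan"), float("nan"))
    spearman_b: tuple[float, float] = (float("nan"), float("nan"))

    def to_dict(self) -> dict:
        return {
            "groups": [self.label_a, self.label_b],
            "red_rates": {self.label_a: list(map(float, self.red_rates_a)),
                          self.label_b: list(map(float, self.red_rates_b))},
            "blue_rates": {self.label_a: list(map(float, self.blue_rates_a)),
                           self.label_b: list(map(float, self.blue_rates_b))},
            "auc": {"red": self.auc_red, "blue": self.auc_blue},
            "mann_whitney_p": {"red": self.mw_p_red, "blue": self.mw_p_blue},
            "spearman_blue_vs_red": {self.label_a: list(self.spearman_a),
                                     self.label_b: list(self.spearman_b)},
        }


def compare_rates(
    label_a: str, label_b: str,
    red_rates_a, red_rates_b, blue_rates_a, blue_rates_b,
    fragment_ids_a=None, fragment_ids_b=None,
) -> GroupComparison:
    """Assemble a GroupComparison with tests and correlations filled in."""
    red_a = np.asarray(red_rates_a, dtype=float)
    red_b = np.asarray(red_rates_b, dtype=float)
    blue_a = np.asarray(blue_rates_a, dtype=float)
    blue_b = np.asarray(blue_rates_b, dtype=float)
    _, p_red = mann_whitney(red_a, red_b)
    _, p_blue = mann_whitney(blue_a, blue_b)
    return GroupComparison(
        label_a=label_a, label_b=label_b,
        red_rates_a=red_a, red_rates_b=red_b,
        blue_rates_a=blue_a, blue_rates_b=blue_b,
        fragment_ids_a=list(fragment_ids_a or []),
        fragment_ids_b=list(fragment_ids_b or []),
        auc_red=roc_auc(red_a, red_b),
        auc_blue=roc_auc(blue_a, blue_b),
        mw_p_red=p_red, mw_p_blue=p_blue,
        spearman_a=spearman(blue_a, red_a) if red_a.size >= 3 else (np.nan, np.nan),
        spearman_b=spearman(blue_b, red_b) if red_b.size >= 3 else (np.nan, np.nan),
    )


def overlap_coefficient(rates_a, rates_b, bins) -> float:
    """Overlap of two rate histograms: sum of min of the two proportions."""
    ha, _ = np.histogram(rates_a, bins=bins)
    hb, _ = np.histogram(rates_b, bins=bins)
    pa = ha / max(ha.sum(), 1)
    pb = hb / max(hb.sum(), 1)
    return float(np.minimum(pa, pb).sum())


def _fd_bins(pooled: np.ndarray, min_bins: int = 10) -> np.ndarray:
    """Freedman-Diaconis bin edges on pooled rates, at least min_bins."""
    pooled = np.asarray(pooled, dtype=float)
    lo, hi = float(pooled.min()), float(pooled.max())
    if hi <= lo:
        hi = lo + 1.0
    iqr = np.subtract(*np.percentile(pooled, [75, 25]))
    width = 2 * iqr / np.cbrt(pooled.size) if iqr > 0 else 0.0
    n_bins = int(np.ceil((hi - lo) / width)) if width > 0 else min_bins
    return np.linspace(lo, hi, max(n_bins, min_bins) + 1)


def rate_histograms(comparison: GroupComparison, which: str = "red",
                    bins=None, path_prefix: str | None = None):
    """Binned per-fragment rate counts per group, with overlap statistic.

    Returns (DataFrame, overlap).  When *path_prefix* is given, writes
    ``<prefix>.csv`` and ``<prefix>.png``.
    """
    ra = getattr(comparison, f"{which}_rates_a")
    rb = getattr(comparison, f"{which}_rates_b")
    if bins is None:
        bins = _fd_bins(np.concatenate([ra, rb]))
    ha, edges = np.histogram(ra, bins=bins)
    hb, _ = np.histogram(rb, bins=bins)
    table = pd.DataFrame({
        "bin_left": edges[:-1], "bin_right": edges[1:],
        comparison.label_a: ha, comparison.label_b: hb,
    })
    overlap = overlap_coefficient(ra, rb, bins)
    if path_prefix is not None:
        table.to_csv(f"{path_prefix}.csv", index=False)
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 4))
        centers = (edges[:-1] + edges[1:]) / 2
        w = (edges[1] - edges[0]) * 0.45
        ax.bar(centers - w / 2, ha, width=w, color="purple", label=comparison.label_a)
        ax.bar(centers + w / 2, hb, width=w, color="green", label=comparison.label_b)
        ax.set_xlabel(f"{which} wave trains per second")
        ax.set_ylabel("number of fragments")
        ax.legend()
        fig.tight_layout()
        fig.savefig(f"{path_prefix}.png", dpi=120)
        plt.close(fig)
    return table, overlap


def rate_scatter(comparison: GroupComparison, path_prefix: str | None = None) -> pd.DataFrame:
    """One point per fragment: (red rate, blue rate, group)."""
    rows = []
    for ids, red, blue, grp in (
        (comparison.fragment_ids_a, comparison.red_rates_a, comparison.blue_rates_a,
         comparison.label_a),
        (comparison.fragment_ids_b, comparison.red_rates_b, comparison.blue_rates_b,
         comparison.label_b),
    ):
        ids = list(ids) if ids else [f"{grp}_{k}" for k in range(len(red))]
        for fid, r, b in zip(ids, red, blue):
            rows.append({"fragment_id": fid, "group": grp,
                         "red_rate": float(r), "blue_rate": float(b)})
    table = pd.DataFrame(rows, columns=["fragment_id", "group", "red_rate", "blue_rate"])
    if path_prefix is not None:
        table.to_csv(f"{path_prefix}.csv", index=False)
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 5))
        for grp, marker, color in ((comparison.label_a, "D", "purple"),
                                   (comparison.label_b, "o", "green")):
            sel = table[table.group == grp]
            ax.scatter(sel.red_rate, sel.blue_rate, marker=marker, color=color, label=grp)
        ax.set_xlabel("wave trains per second in the red area")
        ax.set_ylabel("wave trains per second in the blue area")
        ax.legend()
        fig.tight_layout()
        fig.savefig(f"{path_prefix}.png", dpi=120)
        plt.close(fig)
    return table
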