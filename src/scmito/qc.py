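"""Coverage-uniformity metrics: per-base depth, Lorenz curve, Gini, breadth.

The Lorenz curve plots the cumulative fraction of genome positions (sorted by
ascending depth) against the cumulative fraction of sequenced bases; the
diagonal is perfectly uniform coverage and the Gini coefficient
(1 - 2 x area under the curve, trapezoidal rule) summarizes the deviation.
By default all genome positions enter the curve, zeros included; pass
``covered_only=True`` to restrict to positions with nonzero depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .align import Alignment
from .call import Pileup


def depth_profile(source, length: int) -> np.ndarray:
    """Per-base depth vector of the circular genome.

    ``source`` may be a :class:`Pileup` (quality-filtered depth) or an
    iterable of :class:`Alignment` (every reference-consuming base counts).
    """
    if isinstance(source, Pileup):
        if source.length != length:
            raise ValueError("pileup length mismatch")
        return source.filtered_depth.copy()
    diff = np.zeros(length + 1, dtype=np.int64)
    for a in source:
        ref_cur = a.start - 1
        if not 0 <= ref_cur < length:
            raise ValueError(f"alignment start {a.start} outside [1, {length}]")
        for op, n in a.cigar:
            if op in "MD":
                s = ref_cur % length
                e = s + n
                diff[s] += 1
                diff[min(e, length)] -= 1
                if e > length:
                    diff[0] += 1
                    diff[e - length] -= 1
                ref_cur += n
    return np.cumsum(diff[:length])


@dataclass
class LorenzCurve:
    x: np.ndarray  # cumulative fraction of positions, ascending depth
    y: np.ndarray  # cumulative fraction of total depth
    gini: float

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("cum_fraction_positions\tcum_fraction_reads\n")
            for xi, yi in zip(self.x, self.y):
                fh.write(f"{xi:.6f}\t{yi:.6f}\n")


def lorenz(profile: np.ndarray, covered_only: bool = False) -> LorenzCurve:
    """Lorenz curve and Gini coefficient of a depth profile."""
    d = np.asarray(profile, dtype=float)
    if covered_only:
        d = d[d > 0]
    if d.size == 0 or d.sum() <= 0:
        raise ValueError("cannot compute a Lorenz curve for an all-zero depth profile")
    if (d < 0).any():
        raise ValueError("negative depths")
    d = np.sort(d)
    n = d.size
    x = np.arange(n + 1) / n
    y = np.concatenate([[0.0], np.cumsum(d)]) / d.sum()
    auc = float(np.trapezoid(y, x))
    return LorenzCurve(x=x, y=y, gini=1.0 - 2.0 * auc)


def gini(profile: np.ndarray, covered_only: bool = False) -> float:
    return lorenz(profile, covered_only=covered_only).gini


def coverage_stats(profile: np.ndarray, min_depth: int) -> dict:
    """Breadth (% positions at or above min_depth) and mean per-base depth."""
    d = np.asarray(profile)
    if d.size == 0:
        raise ValueError("empty profile")
    return {
        "breadth_pct": 100.0 * float((d >= min_depth).mean()),
        "mean_depth": float(d.mean()),
    }


def plot_lorenz(curves: dict[str, LorenzCurve], path: str | Path) -> None:
    """Write a Lorenz-curve comparison figure (one line per label)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, c in curves.items():
        ax.plot(c.x, c.y, label=f"{label} (Gini {c.gini:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="uniform")
    ax.set_xlabel("cumulative fraction of genome")
    ax.set_ylabel("cumulative fraction of reads")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
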