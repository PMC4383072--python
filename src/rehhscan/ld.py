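"""Pairwise r-squared from phased haplotypes and the breed-level LD decay curve."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedStatisticError
from .types import HaplotypeSet, MarkerMap


def haplotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """r^2 between two phased 0/1 haplotype columns.

    r^2 = (p_AB - p_A p_B)^2 / (p_A (1-p_A) p_B (1-p_B)); equals the squared
    Pearson correlation of the columns. Raises for monomorphic input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UndefinedStatisticError("columns must be 1-D and equal length")
    pa = x.mean()
    pb = y.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise UndefinedStatisticError("LD undefined for monomorphic column")
    pab = (x * y).mean()
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


@dataclass
class LDDecayCurve:
    """Mean r^2 per physical-distance bin over (0, max_dist]."""

    bin_edges: np.ndarray    # length B+1, bin b covers (edges[b], edges[b+1]]
    mean_r2: np.ndarray      # NaN for empty bins
    n_pairs: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "bin_start": self.bin_edges[:-1],
            "bin_end": self.bin_edges[1:],
            "mean_r2": self.mean_r2,
            "n_pairs": self.n_pairs,
        })


def ld_decay(hs: HaplotypeSet, mmap: MarkerMap, max_dist: float = 1_000_000,
             bin_width: float = 50_000) -> LDDecayCurve:
    """Bin all intra-chromosomal polymorphic pairs within ``max_dist`` by distance.

    Distance-0 pairs (duplicated positions cannot occur on a valid map) would
    fall in the first bin.
    """
    edges = np.arange(0, max_dist + bin_width, bin_width, dtype=float)
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    H = hs.hap.astype(np.float64)
    for lo, hi in mmap.chrom_slices().values():
        sub = H[:, lo:hi]
        pos = mmap.pos_bp[lo:hi].astype(float)
        p = sub.mean(axis=0)
        poly = (p > 0) & (p < 1)
        m = hi - lo
        for d in range(1, m):
            dist = pos[d:] - pos[:-d]
            inside = dist <= max_dist
            if not inside.any():
                break
            ok = inside & poly[:-d] & poly[d:]
            if not ok.any():
                continue
            x = sub[:, :-d][:, ok]
            y = sub[:, d:][:, ok]
            pa = x.mean(axis=0)
            pb = y.mean(axis=0)
            pab = (x * y).mean(axis=0)
            num = (pab - pa * pb) ** 2
            den = pa * (1 - pa) * pb * (1 - pb)
            r2 = num / den
            # left-open right-closed bins: (0, w], (w, 2w], ...
            b = np.ceil(dist[ok] / bin_width).astype(int) - 1
            b = np.clip(b, 0, n_bins - 1)
            np.add.at(sums, b, r2)
            np.add.at(counts, b, 1)

    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDDecayCurve(edges, mean, counts)
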