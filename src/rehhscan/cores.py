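"""Automatic core-haplotype selection.

A core region is a contiguous marker span of ``min_snps``..``max_snps`` markers
in which at least ``strong_frac`` of the informative marker pairs are in strong
LD, judged by a likelihood confidence interval on |D'| (Gabriel-style block
rule). Candidate spans are accepted greedily by descending marker count (ties:
descending bp length, then ascending position) subject to non-overlap; this
greedy order provably yields the lexicographically best non-overlapping set
under the same ordering, which is what the brute-force oracle checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedStatisticError
from .types import HaplotypeSet, MarkerMap

STRONG, RECOMB, INCONCLUSIVE = 1, 2, 0

_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class BlockRule:
    """Thresholds of the D' confidence-interval block definition."""

    ci_lower_strong: float = 0.70
    ci_upper_strong: float = 0.98
    ci_upper_recomb: float = 0.90
    strong_frac: float = 0.95
    ci_mass: float = 0.90  # central CI mass (90% -> 5% / 95% quantiles)


@dataclass
class DPrimeCI:
    dprime: float   # |D'| point estimate
    lower: float
    upper: float


@dataclass
class CoreRegion:
    chrom: str
    start_idx: int  # global marker index, inclusive
    end_idx: int    # inclusive
    start_bp: int
    end_bp: int

    @property
    def n_snps(self) -> int:
        return self.end_idx - self.start_idx + 1

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class CoreAllele:
    region: CoreRegion
    allele: str            # 0/1 string over the core markers
    count: int             # carrier count c_t
    frequency: float
    carrier_rows: np.ndarray


# ---------------------------------------------------------------------------
# |D'| confidence intervals
# ---------------------------------------------------------------------------


def _dprime_hat(n11, n10, n01, n00):
    n = n11 + n10 + n01 + n00
    pa = (n11 + n10) / n
    pb = (n11 + n01) / n
    d = n11 / n - pa * pb
    pos = d >= 0
    dmax = np.where(pos,
                    np.minimum(pa * (1 - pb), (1 - pa) * pb),
                    np.minimum(pa * pb, (1 - pa) * (1 - pb)))
    return d, dmax, pa, pb


def dprime_ci_batch(n11, n10, n01, n00, ci_mass: float = 0.90) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized |D'| estimate and likelihood CI for arrays of haplotype counts.

    The likelihood of the 2x2 haplotype table is profiled over a 101-point
    |D'| grid with marginal allele frequencies fixed at their MLEs; the CI is
    read off the normalized likelihood mass.
    """
    n11 = np.asarray(n11, dtype=float)
    n10 = np.asarray(n10, dtype=float)
    n01 = np.asarray(n01, dtype=float)
    n00 = np.asarray(n00, dtype=float)
    d, dmax, pa, pb = _dprime_hat(n11, n10, n01, n00)
    sign = np.where(d >= 0, 1.0, -1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dp_hat = np.abs(d) / dmax
    dp_hat = np.clip(np.nan_to_num(dp_hat), 0.0, 1.0)

    # (P, G) haplotype frequencies along the grid
    dd = sign[:, None] * _GRID[None, :] * dmax[:, None]
    f11 = pa[:, None] * pb[:, None] + dd
    f10 = pa[:, None] * (1 - pb[:, None]) - dd
    f01 = (1 - pa[:, None]) * pb[:, None] - dd
    f00 = (1 - pa[:, None]) * (1 - pb[:, None]) + dd
    eps = 1e-12
    ll = (n11[:, None] * np.log(np.maximum(f11, eps))
          + n10[:, None] * np.log(np.maximum(f10, eps))
          + n01[:, None] * np.log(np.maximum(f01, eps))
          + n00[:, None] * np.log(np.maximum(f00, eps)))
    ll -= ll.max(axis=1, keepdims=True)
    w = np.exp(ll)
    w /= w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1)
    tail = (1.0 - ci_mass) / 2.0
    lower = _GRID[np.argmax(cum >= tail, axis=1)]
    upper = _GRID[np.argmax(cum >= 1.0 - tail, axis=1)]
    return dp_hat, lower, upper


def dprime_ci(n11: int, n10: int, n01: int, n00: int, ci_mass: float = 0.90) -> DPrimeCI:
    """|D'| point estimate with likelihood CI for one pair of markers."""
    na = n11 + n10
    nb = n11 + n01
    n = n11 + n10 + n01 + n00
    if n == 0 or na in (0, n) or nb in (0, n):
        raise UndefinedStatisticError("|D'| undefined for monomorphic marker")
    dp, lo, hi = dprime_ci_batch([n11], [n10], [n01], [n00], ci_mass)
    return DPrimeCI(float(dp[0]), float(lo[0]), float(hi[0]))


def classify_pair(ci: DPrimeCI, rule: BlockRule | None = None) -> str:
    """Gabriel-style pair call: strong_LD / recombination / inconclusive."""
    rule = rule or BlockRule()
    if ci.lower >= rule.ci_lower_strong and ci.upper >= rule.ci_upper_strong:
        return "strong_LD"
    if ci.upper < rule.ci_upper_recomb:
        return "recombination"
    return "inconclusive"


def _classify_batch(lower, upper, rule: BlockRule) -> np.ndarray:
    cls = np.full(lower.shape, INCONCLUSIVE, dtype=np.int8)
    cls[(lower >= rule.ci_lower_strong) & (upper >= rule.ci_upper_strong)] = STRONG
    cls[upper < rule.ci_upper_recomb] = RECOMB
    # strong wins if both matched (cannot happen: upper >= 0.98 excludes < 0.90)
    return cls


# ---------------------------------------------------------------------------
# Core finding
# ---------------------------------------------------------------------------


def pair_classes(hap: np.ndarray, max_span: int, rule: BlockRule) -> dict[int, np.ndarray]:
    """Class of every marker pair (i, i+d) for d = 1..max_span-1 within one chromosome.

    Returns ``{d: classes}`` with ``classes[i]`` the call for pair (i, i+d);
    pairs involving a monomorphic marker are inconclusive (uninformative).
    """
    H = hap.astype(np.int64)
    m = H.shape[1]
    p = H.mean(axis=0)
    poly = (p > 0) & (p < 1)
    out: dict[int, np.ndarray] = {}
    for d in range(1, min(max_span, m)):
        x = H[:, : m - d]
        y = H[:, d:]
        n11 = (x & y).sum(axis=0)
        n10 = (x & (1 - y)).sum(axis=0)
        n01 = ((1 - x) & y).sum(axis=0)
        n00 = ((1 - x) & (1 - y)).sum(axis=0)
        ok = poly[: m - d] & poly[d:]
        cls = np.full(m - d, INCONCLUSIVE, dtype=np.int8)
        if ok.any():
            _, lo, hi = dprime_ci_batch(n11[ok], n10[ok], n01[ok], n00[ok], rule.ci_mass)
            cls[ok] = _classify_batch(lo, hi, rule)
        out[d] = cls
    return out


def candidate_spans(classes: dict[int, np.ndarray], m: int, min_snps: int,
                    max_snps: int, strong_frac: float) -> list[tuple[int, int]]:
    """All (start, length) spans whose informative pairs are >= strong_frac strong.

    Spans with zero informative pairs are not candidates. Enumerating every
    admissible span of length min..max subsumes the trim-overlong-run rule:
    a run longer than max_snps contributes its length-max_snps sub-spans.
    """
    # prefix sums of strong / informative counts per offset
    strong_cum: dict[int, np.ndarray] = {}
    info_cum: dict[int, np.ndarray] = {}
    for d, cls in classes.items():
        strong_cum[d] = np.concatenate([[0], np.cumsum(cls == STRONG)])
        info_cum[d] = np.concatenate([[0], np.cumsum(cls != INCONCLUSIVE)])
    spans = []
    for L in range(min_snps, min(max_snps, m) + 1):
        n_start = m - L + 1
        strong = np.zeros(n_start, dtype=np.int64)
        info = np.zeros(n_start, dtype=np.int64)
        for d in range(1, L):
            sc, ic = strong_cum[d], info_cum[d]
            # pairs (i, i+d) inside [a, a+L-1]: i in [a, a+L-1-d]
            strong += sc[L - d : L - d + n_start] - sc[:n_start]
            info += ic[L - d : L - d + n_start] - ic[:n_start]
        ok = (info > 0) & (strong >= strong_frac * info)
        spans.extend((int(a), L) for a in np.flatnonzero(ok))
    return spans


def select_spans(spans: list[tuple[int, int]], pos_bp: np.ndarray) -> list[tuple[int, int]]:
    """Greedy non-overlapping selection by (-n_markers, -bp_length, start_bp)."""

    def key(span):
        a, L = span
        return (-L, -(int(pos_bp[a + L - 1]) - int(pos_bp[a])), int(pos_bp[a]), a)

    chosen: list[tuple[int, int]] = []
    occupied = np.zeros(len(pos_bp), dtype=bool)
    for a, L in sorted(spans, key=key):
        if not occupied[a : a + L].any():
            chosen.append((a, L))
            occupied[a : a + L] = True
    return sorted(chosen)


def find_cores(hs: HaplotypeSet, mmap: MarkerMap, min_snps: int = 3, max_snps: int = 20,
               rule: BlockRule | None = None) -> list[CoreRegion]:
    """Detect non-overlapping core regions of ``min_snps``..``max_snps`` markers."""
    rule = rule or BlockRule()
    if hs.n_markers != len(mmap):
        raise UndefinedStatisticError("haplotype matrix and map disagree on marker count")
    regions: list[CoreRegion] = []
    for chrom, (lo, hi) in mmap.chrom_slices().items():
        m = hi - lo
        if m < min_snps:
            continue
        classes = pair_classes(hs.hap[:, lo:hi], max_snps, rule)
        spans = candidate_spans(classes, m, min_snps, max_snps, rule.strong_frac)
        for a, L in select_spans(spans, mmap.pos_bp[lo:hi]):
            s, e = lo + a, lo + a + L - 1
            regions.append(CoreRegion(chrom, s, e, int(mmap.pos_bp[s]), int(mmap.pos_bp[e])))
    return regions


def core_alleles(region: CoreRegion, hs: HaplotypeSet) -> list[CoreAllele]:
    """Distinct haplotype variants over the core markers with carrier counts.

    Alleles are ordered by descending frequency (ties: allele string), so the
    most frequent variant is first ("H1"). Frequencies sum to 1.
    """
    sub = hs.hap[:, region.start_idx : region.end_idx + 1]
    strings = np.array(["".join(map(str, row)) for row in sub], dtype=object)
    labels, inverse, counts = np.unique(strings, return_inverse=True, return_counts=True)
    order = sorted(range(len(labels)), key=lambda i: (-counts[i], labels[i]))
    total = sub.shape[0]
    out = []
    for i in order:
        rows = np.flatnonzero(inverse == i)
        out.append(CoreAllele(region, str(labels[i]), int(counts[i]), counts[i] / total, rows))
    return out
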