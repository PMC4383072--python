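"""EHH decay, pooled-other EHH, relative EHH, and bifurcation trees.

EHH of a core allele with c_t carriers at extension x is the probability that
two distinct randomly chosen carriers are identical by state over the whole
interval from the core edge to x:

    EHH = sum_i C(e_i, 2) / C(c_t, 2)

where e_i are the multiplicities of the distinct extended haplotypes. The
pooled control statistic uses the same form summed over all non-tested core
alleles, grouping extensions within each of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cores import CoreAllele, CoreRegion
from .errors import MissingMarkerError, UndefinedStatisticError
from .types import HaplotypeSet, MarkerMap

UPSTREAM = "upstream"
DOWNSTREAM = "downstream"

#: rEHH sentinel when the pooled EHH is 0 while the tested EHH is positive.
REHH_INF = float("inf")


def _pairs(counts: np.ndarray) -> float:
    c = np.asarray(counts, dtype=np.int64)
    return float((c * (c - 1) // 2).sum())


class _Extender:
    """Incrementally refines a haplotype partition marker by marker.

    The denominator (homozygous pairs within the *initial* grouping) is fixed;
    stepping through markers only ever splits groups, so EHH is non-increasing
    by construction.
    """

    def __init__(self, initial_ids: np.ndarray):
        ids = np.asarray(initial_ids, dtype=np.int64)
        _, self.ids = np.unique(ids, return_inverse=True)
        self.denom = _pairs(np.bincount(self.ids))
        if self.denom < 1:
            raise UndefinedStatisticError("EHH undefined for fewer than 2 haplotypes")
        self._num = self.denom

    def step(self, column: np.ndarray) -> float:
        merged = self.ids * 2 + np.asarray(column, dtype=np.int64)
        _, self.ids = np.unique(merged, return_inverse=True)
        self._num = _pairs(np.bincount(self.ids))
        return self.ehh

    @property
    def ehh(self) -> float:
        return self._num / self.denom


def ehh_at(extended: np.ndarray) -> float:
    """EHH from a carriers x interval-markers matrix (rows = carrier haplotypes)."""
    ext = np.asarray(extended)
    if ext.ndim != 2:
        raise UndefinedStatisticError("expected a 2-D carriers x markers matrix")
    c = ext.shape[0]
    if c < 2:
        raise UndefinedStatisticError("EHH undefined for fewer than 2 carriers")
    e = _Extender(np.zeros(c, dtype=np.int64))
    for j in range(ext.shape[1]):
        e.step(ext[:, j])
    return e.ehh


def ehh_pooled_others(groups: list[np.ndarray]) -> float:
    """Pooled EHH of the non-tested core alleles.

    ``groups`` holds one carriers x interval matrix per other core allele;
    extensions are grouped within each allele (haplotypes of different core
    alleles are never counted as homozygous pairs).
    """
    total = sum(g.shape[0] for g in groups)
    if total < 2:
        raise UndefinedStatisticError("pooled EHH undefined for fewer than 2 haplotypes")
    ids = np.concatenate([np.full(g.shape[0], k, dtype=np.int64) for k, g in enumerate(groups)])
    e = _Extender(ids)
    if groups and groups[0].ndim == 2 and groups[0].shape[1]:
        cols = np.vstack(groups)
        for j in range(cols.shape[1]):
            e.step(cols[:, j])
    return e.ehh


# ---------------------------------------------------------------------------
# Decay curves
# ---------------------------------------------------------------------------


@dataclass
class EHHCurve:
    direction: str
    marker_idx: np.ndarray  # global marker indices sampled (edge excluded)
    dist_bp: np.ndarray
    dist_cm: np.ndarray
    ehh: np.ndarray         # EHH at each sampled marker; edge value is 1 by definition

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "direction": self.direction,
            "marker_idx": self.marker_idx,
            "dist_bp": self.dist_bp,
            "dist_cm": self.dist_cm,
            "ehh": self.ehh,
        })


def _edge_and_steps(region: CoreRegion, mmap: MarkerMap, direction: str) -> tuple[int, range]:
    lo, hi = mmap.chrom_slices()[str(region.chrom)]
    if direction == UPSTREAM:
        edge = region.start_idx
        return edge, range(edge - 1, lo - 1, -1)
    if direction == DOWNSTREAM:
        edge = region.end_idx
        return edge, range(edge + 1, hi)
    raise ValueError(f"direction must be {UPSTREAM!r} or {DOWNSTREAM!r}")


def ehh_decay(hs: HaplotypeSet, mmap: MarkerMap, allele: CoreAllele, direction: str,
              stop_ehh: float = 0.05) -> EHHCurve:
    """EHH at successive markers outward from the core edge until EHH < stop_ehh
    (the stopping sample is included) or the chromosome end."""
    if allele.count < 2:
        raise UndefinedStatisticError("EHH undefined for a singleton core allele")
    edge, steps = _edge_and_steps(allele.region, mmap, direction)
    ext = _Extender(np.zeros(allele.count, dtype=np.int64))
    idxs, vals = [], []
    for j in steps:
        v = ext.step(hs.hap[allele.carrier_rows, j])
        idxs.append(j)
        vals.append(v)
        if v < stop_ehh:
            break
    idxs = np.array(idxs, dtype=np.int64)
    dist_bp = np.abs(mmap.pos_bp[idxs] - mmap.pos_bp[edge]) if len(idxs) else np.array([], dtype=np.int64)
    dist_cm = np.abs(mmap.pos_cm[idxs] - mmap.pos_cm[edge]) if len(idxs) else np.array([])
    return EHHCurve(direction, idxs, dist_bp, dist_cm, np.array(vals))


# ---------------------------------------------------------------------------
# rEHH
# ---------------------------------------------------------------------------


@dataclass
class REHHValue:
    rehh: float          # may be REHH_INF; NaN if undefined (both EHH zero)
    ehh_t: float
    ehh_pooled: float
    marker_idx: int
    dist_cm: float


def nearest_test_marker(region: CoreRegion, mmap: MarkerMap, direction: str,
                test_distance_cm: float = 0.25) -> int:
    """Outward marker whose genetic distance from the core edge is nearest to
    ``test_distance_cm`` (ties: the farther marker). Raises if the nearest
    distance exceeds twice the target."""
    edge, steps = _edge_and_steps(region, mmap, direction)
    idxs = np.array(list(steps), dtype=np.int64)
    if len(idxs) == 0:
        raise MissingMarkerError(f"no {direction} markers beyond the core")
    dist = np.abs(mmap.pos_cm[idxs] - mmap.pos_cm[edge])
    gap = np.abs(dist - test_distance_cm)
    best = np.flatnonzero(gap == gap.min())
    j = int(idxs[best[np.argmax(dist[best])]])
    if gap.min() > test_distance_cm:  # nothing within 2x the test distance
        raise MissingMarkerError(
            f"nearest {direction} marker is {dist[best[0]]:.4f} cM from the core edge"
        )
    return j


def rehh(hs: HaplotypeSet, mmap: MarkerMap, alleles: list[CoreAllele], t_index: int,
         direction: str, test_distance_cm: float = 0.25) -> REHHValue:
    """Relative EHH of core allele ``alleles[t_index]`` vs pooled others.

    rEHH = EHH_t / EHH_pooled at the test marker. Returns ``inf`` when
    EHH_pooled = 0 < EHH_t and NaN when both are 0 (flagged, never dropped
    silently).
    """
    t = alleles[t_index]
    if t.count < 2:
        raise UndefinedStatisticError("rEHH undefined for a singleton core allele")
    others = [a for k, a in enumerate(alleles) if k != t_index]
    if sum(a.count for a in others) < 2:
        raise UndefinedStatisticError("rEHH undefined with fewer than 2 non-carrier haplotypes")
    region = t.region
    j = nearest_test_marker(region, mmap, direction, test_distance_cm)
    edge = region.start_idx if direction == UPSTREAM else region.end_idx
    cols = (np.arange(j, edge) if direction == UPSTREAM else np.arange(edge + 1, j + 1))

    ehh_t = ehh_at(hs.hap[np.ix_(t.carrier_rows, cols)]) if len(cols) else 1.0
    ehh_p = ehh_pooled_others([hs.hap[np.ix_(a.carrier_rows, cols)] for a in others])
    if ehh_p > 0:
        r = ehh_t / ehh_p
    elif ehh_t > 0:
        r = REHH_INF
    else:
        r = float("nan")
    return REHHValue(r, ehh_t, ehh_p, j, float(abs(mmap.pos_cm[j] - mmap.pos_cm[edge])))


# ---------------------------------------------------------------------------
# Bifurcation trees
# ---------------------------------------------------------------------------


@dataclass
class BifurcationNode:
    count: int
    children: dict = field(default_factory=dict)  # allele char -> BifurcationNode

    def to_dict(self) -> dict:
        return {"count": self.count,
                "children": {k: v.to_dict() for k, v in self.children.items()}}


@dataclass
class BifurcationTree:
    allele: str
    direction: str
    root: BifurcationNode

    def to_dict(self) -> dict:
        return {"core_allele": self.allele, "direction": self.direction,
                "tree": self.root.to_dict()}


def bifurcation(hs: HaplotypeSet, mmap: MarkerMap, allele: CoreAllele, direction: str,
                max_markers: int = 20) -> BifurcationTree:
    """Tree of extended-haplotype splits outward from the core; child counts sum
    to their parent's count at every depth."""
    if allele.count < 2:
        raise UndefinedStatisticError("bifurcation undefined for a singleton core allele")
    _, steps = _edge_and_steps(allele.region, mmap, direction)
    cols = list(steps)[:max_markers]

    def build(rows: np.ndarray, depth: int) -> BifurcationNode:
        node = BifurcationNode(count=len(rows))
        if depth >= len(cols) or len(rows) == 0:
            return node
        col = hs.hap[rows, cols[depth]]
        for val in (0, 1):
            sub = rows[col == val]
            if len(sub):
                node.children[str(val)] = build(sub, depth + 1)
        return node

    root = build(np.asarray(allele.carrier_rows), 0)
    return BifurcationTree(allele.allele, direction, root)
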