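"""Cross-breed alignment of significant cores, shared-region extraction,
per-chromosome summaries, and gene overlap.

Two significant cores "share" when they contain at least one common marker id.
Connected components of the sharing graph that span >= 2 breeds of the same
production group become SharedRegions; the region interval is the union
(bounding interval) of the member core intervals. A dual-purpose breed may
belong to several groups and is compared within each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cores import CoreRegion
from .errors import ConfigError, MapMismatchError, NamespaceError
from .types import GeneAnnotation, MarkerMap, _chrom_sort_key


@dataclass
class ProductionGroup:
    name: str
    breeds: list[str]

    def __post_init__(self):
        if len(self.breeds) < 2:
            raise ConfigError(f"group {self.name!r} needs >= 2 breeds")


@dataclass
class SharedRegion:
    group: str
    chrom: str
    start_bp: int
    end_bp: int
    breeds: list[str]
    core_ids: list[str]           # "<breed>:<core index>" of contributing cores
    shared_snps: list[str]        # marker ids present in cores of >= 2 breeds
    genes: list[str] = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def shared_regions(sig_cores: dict[str, list[CoreRegion]], group: ProductionGroup,
                   maps: dict[str, MarkerMap]) -> list[SharedRegion]:
    """Shared regions of one production group from per-breed significant cores.

    ``sig_cores`` maps breed -> significant CoreRegions; all group members must
    be on the same marker map. Output is ordered by (chrom, start_bp) and is
    invariant to breed input order.
    """
    members = [b for b in group.breeds if b in sig_cores]
    if len(members) < 2:
        return []
    ref = maps[members[0]]
    for b in members[1:]:
        if not ref.same_markers(maps[b]):
            raise MapMismatchError(f"breeds {members[0]!r} and {b!r} are on different maps")

    nodes = []  # (breed, core_id, region, marker id frozenset)
    for b in sorted(members):
        for k, region in enumerate(sig_cores[b]):
            snps = frozenset(ref.marker_id[region.start_idx : region.end_idx + 1])
            nodes.append((b, f"{b}:{k}", region, snps))

    uf = _UnionFind(len(nodes))
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if nodes[i][3] & nodes[j][3]:
                uf.union(i, j)

    comps: dict[int, list[int]] = {}
    for i in range(len(nodes)):
        comps.setdefault(uf.find(i), []).append(i)

    out = []
    for comp in comps.values():
        breeds = sorted({nodes[i][0] for i in comp})
        if len(breeds) < 2:
            continue
        regions = [nodes[i][2] for i in comp]
        chroms = {str(r.chrom) for r in regions}
        # members share SNPs, so a component lives on one chromosome
        chrom = chroms.pop()
        shared: set[str] = set()
        for a in range(len(comp)):
            for b in range(a + 1, len(comp)):
                ia, ib = comp[a], comp[b]
                if nodes[ia][0] != nodes[ib][0]:
                    shared |= nodes[ia][3] & nodes[ib][3]
        pos = {str(m): int(p) for m, p in zip(ref.marker_id, ref.pos_bp)}
        out.append(SharedRegion(
            group=group.name,
            chrom=chrom,
            start_bp=min(r.start_bp for r in regions),
            end_bp=max(r.end_bp for r in regions),
            breeds=breeds,
            core_ids=sorted(nodes[i][1] for i in comp),
            shared_snps=sorted(shared, key=lambda m: pos.get(m, 0)),
        ))
    out.sort(key=lambda r: (_chrom_sort_key(r.chrom), r.start_bp))
    return out


def summarize_regions(regions: list[SharedRegion], mmap: MarkerMap) -> pd.DataFrame:
    """Per-chromosome and total counts, summed/mean bp size, and genome fraction.

    The genome denominator is the mapped span: sum over chromosomes of
    (last - first marker bp).
    """
    spans = {}
    for chrom, (lo, hi) in mmap.chrom_slices().items():
        spans[chrom] = int(mmap.pos_bp[hi - 1] - mmap.pos_bp[lo])
    genome_bp = sum(spans.values())

    rows = []
    by_chrom: dict[str, list[SharedRegion]] = {}
    for r in regions:
        by_chrom.setdefault(str(r.chrom), []).append(r)
    for chrom in sorted(spans, key=_chrom_sort_key):
        rs = by_chrom.get(chrom, [])
        total = sum(r.length_bp for r in rs)
        rows.append({
            "chrom": chrom,
            "n_regions": len(rs),
            "sum_bp": total,
            "mean_bp": (total / len(rs)) if rs else 0.0,
            "genome_fraction": (total / genome_bp) if genome_bp else 0.0,
        })
    grand = sum(r.length_bp for r in regions)
    rows.append({
        "chrom": "TOTAL",
        "n_regions": len(regions),
        "sum_bp": grand,
        "mean_bp": (grand / len(regions)) if regions else 0.0,
        "genome_fraction": (grand / genome_bp) if genome_bp else 0.0,
    })
    return pd.DataFrame(rows)


def gene_overlap(regions: list[SharedRegion], annotation: GeneAnnotation) -> list[SharedRegion]:
    """Attach overlapping genes (closed-interval intersection) to each region.

    Raises NamespaceError when the chromosome namespaces of regions and
    annotation are completely disjoint (listing the region chromosomes).
    """
    if not regions:
        return regions
    region_chroms = {str(r.chrom) for r in regions}
    ann_chroms = annotation.chroms
    if ann_chroms and region_chroms.isdisjoint(ann_chroms):
        raise NamespaceError(
            f"no region chromosome matches the annotation; offenders: {sorted(region_chroms)}"
        )
    df = annotation.table
    for r in regions:
        sub = df[df["chrom"].astype(str) == str(r.chrom)]
        hit = sub[(sub["start_bp"] <= r.end_bp) & (sub["end_bp"] >= r.start_bp)]
        r.genes = sorted(hit["gene_id"].astype(str).tolist())
    return regions


def regions_frame(regions: list[SharedRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append({
            "group": r.group,
            "chrom": r.chrom,
            "start_bp": r.start_bp,
            "end_bp": r.end_bp,
            "breeds": ",".join(r.breeds),
            "n_breeds": len(r.breeds),
            "core_ids": ",".join(r.core_ids),
            "n_shared_snps": len(r.shared_snps),
            "shared_snps": ",".join(r.shared_snps),
            "genes": ",".join(r.genes),
        })
    return pd.DataFrame(rows)


def write_regions_bed(regions: list[SharedRegion], path) -> None:
    """BED export (0-based half-open) of shared regions."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{r.group}\n")
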