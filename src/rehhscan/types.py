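"""Core domain types: marker map, genotype/haplotype matrices, pedigree, gene annotation.

Conventions
-----------
* Coordinates are 1-based; intervals are closed on both ends.
* Genotypes are minor-allele dosages in {0, 1, 2}; missing is ``MISSING`` (-1).
* Haplotype matrices are binary (0/1) with two consecutive rows per individual:
  rows ``2k`` and ``2k + 1`` belong to sample ``k``.
* The default genetic map is 1 cM/Mb, i.e. ``pos_cm = pos_bp * 1e-6``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DimensionError, PedigreeError

#: Sentinel for a missing genotype call.
MISSING = -1

CM_PER_BP = 1e-6


def _chrom_sort_key(label: str):
    """Numeric chromosomes first in numeric order, then others lexicographically."""
    s = str(label)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


def is_autosome(label: str) -> bool:
    s = str(label)
    return s.isdigit() and int(s) >= 1


@dataclass
class MarkerMap:
    """Ordered marker map: one row per marker, sorted by (chrom, pos_bp)."""

    marker_id: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    pos_cm: np.ndarray

    @classmethod
    def from_arrays(cls, marker_id, chrom, pos_bp, pos_cm=None) -> "MarkerMap":
        marker_id = np.asarray(marker_id, dtype=object)
        chrom = np.asarray([str(c) for c in chrom], dtype=object)
        pos_bp = np.asarray(pos_bp, dtype=np.int64)
        if pos_cm is None:
            pos_cm = pos_bp * CM_PER_BP
        pos_cm = np.asarray(pos_cm, dtype=float)
        if not (len(marker_id) == len(chrom) == len(pos_bp) == len(pos_cm)):
            raise DimensionError("marker map columns have unequal lengths")
        return cls(marker_id, chrom, pos_bp, pos_cm)

    def __len__(self) -> int:
        return len(self.marker_id)

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def sort_order(self) -> np.ndarray:
        """Permutation sorting markers by (chrom, pos_bp)."""
        keys = [(_chrom_sort_key(c), p) for c, p in zip(self.chrom, self.pos_bp)]
        return np.array(sorted(range(len(keys)), key=keys.__getitem__), dtype=np.int64)

    def sorted(self) -> tuple["MarkerMap", np.ndarray]:
        order = self.sort_order()
        mm = MarkerMap(
            self.marker_id[order], self.chrom[order], self.pos_bp[order], self.pos_cm[order]
        )
        return mm, order

    def validate(self) -> None:
        for lo, hi in self.chrom_slices().values():
            d = np.diff(self.pos_bp[lo:hi])
            if np.any(d <= 0):
                raise DimensionError("positions not strictly increasing within chromosome")

    def chrom_slices(self) -> dict[str, tuple[int, int]]:
        """Half-open index span (lo, hi) of each chromosome, in map order."""
        out: dict[str, tuple[int, int]] = {}
        if len(self) == 0:
            return out
        start = 0
        for i in range(1, len(self) + 1):
            if i == len(self) or self.chrom[i] != self.chrom[start]:
                out[str(self.chrom[start])] = (start, i)
                start = i
        return out

    def subset(self, idx) -> "MarkerMap":
        idx = np.asarray(idx)
        return MarkerMap(self.marker_id[idx], self.chrom[idx], self.pos_bp[idx], self.pos_cm[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "pos_cm": self.pos_cm,
            }
        )

    def same_markers(self, other: "MarkerMap") -> bool:
        return len(self) == len(other) and bool(
            np.all(self.marker_id == other.marker_id) and np.all(self.pos_bp == other.pos_bp)
        )


@dataclass
class GenotypeSet:
    """Unphased diploid genotypes: N samples x M markers of minor-allele dosage."""

    sample_ids: np.ndarray
    breeds: np.ndarray
    geno: np.ndarray  # int8, values {0,1,2,MISSING}
    alleles: np.ndarray | None = None  # (M, 2) object array: (major, minor) labels

    def __post_init__(self):
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.breeds = np.asarray(self.breeds, dtype=object)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.ndim != 2:
            raise DimensionError("genotype matrix must be 2-D")
        if len(self.sample_ids) != self.geno.shape[0]:
            raise DimensionError("sample id count does not match genotype rows")
        if len(self.breeds) != self.geno.shape[0]:
            raise DimensionError("breed label count does not match genotype rows")

    @property
    def n_samples(self) -> int:
        return self.geno.shape[0]

    @property
    def n_markers(self) -> int:
        return self.geno.shape[1]

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeSet":
        g = self.geno
        sids, brs, alle = self.sample_ids, self.breeds, self.alleles
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            g = g[sample_idx]
            sids = sids[sample_idx]
            brs = brs[sample_idx]
        if marker_idx is not None:
            marker_idx = np.asarray(marker_idx)
            g = g[:, marker_idx]
            if alle is not None:
                alle = alle[marker_idx]
        return GenotypeSet(sids, brs, g, alle)


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes of one breed: 2N rows x M markers."""

    sample_ids: np.ndarray
    breed: str
    hap: np.ndarray  # uint8 {0,1}

    def __post_init__(self):
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.hap = np.asarray(self.hap, dtype=np.uint8)
        if self.hap.ndim != 2:
            raise DimensionError("haplotype matrix must be 2-D")
        if self.hap.shape[0] % 2 != 0:
            raise DimensionError("haplotype row count must be even")
        if self.hap.shape[0] != 2 * len(self.sample_ids):
            raise DimensionError("haplotype rows != 2 x sample count")
        if self.hap.size and self.hap.max() > 1:
            raise DimensionError("haplotype entries must be 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.hap.shape[0]

    @property
    def n_markers(self) -> int:
        return self.hap.shape[1]

    def to_genotypes(self) -> GenotypeSet:
        g = (self.hap[0::2].astype(np.int8) + self.hap[1::2].astype(np.int8))
        breeds = np.full(self.n_samples, self.breed, dtype=object)
        return GenotypeSet(self.sample_ids.copy(), breeds, g)


@dataclass
class PedigreeTable:
    """Individual / sire / breed records; unknown sire is None."""

    table: pd.DataFrame  # columns: individual, sire, breed

    def __post_init__(self):
        df = self.table
        required = {"individual", "sire", "breed"}
        if not required.issubset(df.columns):
            raise PedigreeError(f"pedigree needs columns {sorted(required)}")
        if df["individual"].duplicated().any():
            dups = df.loc[df["individual"].duplicated(), "individual"].tolist()
            raise PedigreeError(f"duplicated individual ids: {dups}")
        self_sire = df["individual"] == df["sire"]
        if self_sire.any():
            raise PedigreeError(
                f"individuals listed as their own sire: {df.loc[self_sire, 'individual'].tolist()}"
            )

    def sire_of(self) -> dict:
        return {
            r.individual: (None if pd.isna(r.sire) else r.sire)
            for r in self.table.itertuples()
        }


@dataclass
class GeneAnnotation:
    """Gene intervals, 1-based closed coordinates."""

    table: pd.DataFrame  # columns: gene_id, chrom, start_bp, end_bp

    def __post_init__(self):
        df = self.table
        required = {"gene_id", "chrom", "start_bp", "end_bp"}
        if not required.issubset(df.columns):
            raise DimensionError(f"gene annotation needs columns {sorted(required)}")
        if (df["start_bp"] > df["end_bp"]).any():
            raise DimensionError("gene with start_bp > end_bp")

    @property
    def chroms(self) -> set:
        return set(str(c) for c in self.table["chrom"].unique())
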