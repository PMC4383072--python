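"""Two-step quality control (samples, then markers) and relatedness pruning.

Pipeline order is fixed: sample QC (call rate -> replicates -> duo Mendelian
checks) then marker QC (missingness, per-breed missingness, MAF, autosome and
position filters) then, after external phasing, relative pruning that yields
the non-redundant dataset. Defaults follow the documented thresholds:
call rate 0.95, Mendelian rate 0.002, marker missingness 0.025, MAF 0.05,
half-sib family cap 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PedigreeError, UndefinedStatisticError
from .types import MISSING, GenotypeSet, MarkerMap, PedigreeTable, is_autosome


@dataclass
class QCThresholds:
    call_rate: float = 0.95        # exclude samples with rate <= this
    mendel_rate: float = 0.002     # flag duos with error rate >= this
    max_missing: float = 0.025     # exclude markers with missing fraction > this
    maf: float = 0.05              # exclude markers with MAF < this
    family_cap: int = 5
    mendel_drop: str = "son"       # which duo member to drop: "son" or "sire"


@dataclass
class QCReport:
    """Per-cause exclusion bookkeeping; input = retained + sum(excluded) per step."""

    sample_call_rates: dict = field(default_factory=dict)
    excluded_samples: dict = field(default_factory=lambda: {
        "call_rate": [], "replicate": [], "mendelian": [], "family_pruning": []})
    marker_missing_rate: np.ndarray | None = None
    marker_maf: np.ndarray | None = None
    excluded_markers: dict = field(default_factory=lambda: {
        "no_position": [], "non_autosomal": [], "missingness": [], "breed_missing": [], "maf": []})
    replicate_concordances: dict = field(default_factory=dict)
    mendelian_rates: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "excluded_samples": {k: len(v) for k, v in self.excluded_samples.items()},
            "excluded_markers": {k: len(v) for k, v in self.excluded_markers.items()},
        }


# ---------------------------------------------------------------------------
# Per-row statistics
# ---------------------------------------------------------------------------


def sample_call_rate(row: np.ndarray) -> float:
    """Fraction of called (non-missing) genotypes in one sample row."""
    row = np.asarray(row)
    if row.size == 0:
        raise UndefinedStatisticError("call rate undefined for zero markers")
    return float(np.mean(row != MISSING))


def mendelian_error_rate(sire_row: np.ndarray, son_row: np.ndarray) -> float:
    """Duo Mendelian error rate: opposing homozygotes among co-called markers."""
    sire_row = np.asarray(sire_row)
    son_row = np.asarray(son_row)
    if sire_row.shape != son_row.shape:
        raise UndefinedStatisticError("duo rows must share the marker index")
    both = (sire_row != MISSING) & (son_row != MISSING)
    n = int(both.sum())
    if n == 0:
        raise UndefinedStatisticError("no co-called markers in duo")
    opposing = ((sire_row == 0) & (son_row == 2)) | ((sire_row == 2) & (son_row == 0))
    return float((opposing & both).sum() / n)


def replicate_concordance(row_a: np.ndarray, row_b: np.ndarray) -> float:
    """Identity fraction between two genotype rows over co-called markers."""
    row_a = np.asarray(row_a)
    row_b = np.asarray(row_b)
    if row_a.shape != row_b.shape:
        raise UndefinedStatisticError("replicate rows must share the marker index")
    both = (row_a != MISSING) & (row_b != MISSING)
    n = int(both.sum())
    if n == 0:
        raise UndefinedStatisticError("no co-called markers between replicates")
    return float(((row_a == row_b) & both).sum() / n)


# ---------------------------------------------------------------------------
# Step 1: sample QC
# ---------------------------------------------------------------------------


def sample_qc(gset: GenotypeSet, pedigree: PedigreeTable | None = None,
              replicate_pairs: list[tuple[str, str]] | None = None,
              thresholds: QCThresholds | None = None,
              report: QCReport | None = None) -> tuple[np.ndarray, QCReport]:
    """Exclude low-call-rate samples, one member of each replicate pair, and
    the configured member of every high-Mendelian-error duo.

    Returns retained sample indices (into ``gset``) and the QC report.
    """
    th = thresholds or QCThresholds()
    rep = report or QCReport()
    ids = list(gset.sample_ids)
    idx_of = {s: i for i, s in enumerate(ids)}
    excluded: set[str] = set()

    rates = {s: sample_call_rate(gset.geno[i]) for i, s in enumerate(ids)}
    rep.sample_call_rates = rates
    for s in ids:
        if rates[s] <= th.call_rate:
            excluded.add(s)
            rep.excluded_samples["call_rate"].append(s)

    for a, b in (replicate_pairs or []):
        if a in excluded or b in excluded or a not in idx_of or b not in idx_of:
            continue
        conc = replicate_concordance(gset.geno[idx_of[a]], gset.geno[idx_of[b]])
        rep.replicate_concordances[(a, b)] = conc
        if rates[a] < rates[b]:
            drop = a
        elif rates[b] < rates[a]:
            drop = b
        else:
            drop = max(a, b)  # tie: keep the lexicographically smaller id
        excluded.add(drop)
        rep.excluded_samples["replicate"].append(drop)

    if pedigree is not None:
        sire_of = pedigree.sire_of()
        for son in ids:
            sire = sire_of.get(son)
            if sire is None or sire not in idx_of:
                continue
            if son in excluded or sire in excluded:
                continue
            rate = mendelian_error_rate(gset.geno[idx_of[sire]], gset.geno[idx_of[son]])
            rep.mendelian_rates[(sire, son)] = rate
            if rate >= th.mendel_rate:
                drop = son if th.mendel_drop == "son" else sire
                excluded.add(drop)
                rep.excluded_samples["mendelian"].append(drop)

    retained = np.array([i for i, s in enumerate(ids) if s not in excluded], dtype=np.int64)
    return retained, rep


# ---------------------------------------------------------------------------
# Step 2: marker QC
# ---------------------------------------------------------------------------


def marker_qc(gset: GenotypeSet, mmap: MarkerMap,
              thresholds: QCThresholds | None = None,
              report: QCReport | None = None) -> tuple[np.ndarray, QCReport]:
    """Drop markers failing (in priority order): missing position, non-autosomal
    chromosome, whole-dataset missingness, complete missingness in any breed,
    whole-dataset MAF. Each excluded marker is attributed to exactly one cause.
    """
    th = thresholds or QCThresholds()
    rep = report or QCReport()
    g = gset.geno
    n, m = g.shape
    missing = g == MISSING
    miss_rate = missing.mean(axis=0) if n else np.zeros(m)
    with np.errstate(invalid="ignore"):
        called = (~missing).sum(axis=0)
        alt = np.where(g == MISSING, 0, g).sum(axis=0)
        freq = np.divide(alt, 2.0 * called, out=np.full(m, np.nan), where=called > 0)
    maf = np.minimum(freq, 1.0 - freq)
    rep.marker_missing_rate = miss_rate
    rep.marker_maf = maf

    breed_missing = np.zeros(m, dtype=bool)
    for b in np.unique(gset.breeds):
        rows = gset.breeds == b
        breed_missing |= missing[rows].all(axis=0)

    cause = np.full(m, "", dtype=object)
    no_pos = (mmap.pos_bp <= 0)
    non_auto = ~np.array([is_autosome(c) for c in mmap.chrom])
    for j in range(m):
        if no_pos[j]:
            cause[j] = "no_position"
        elif non_auto[j]:
            cause[j] = "non_autosomal"
        elif miss_rate[j] > th.max_missing:
            cause[j] = "missingness"
        elif breed_missing[j]:
            cause[j] = "breed_missing"
        elif np.isnan(maf[j]) or maf[j] < th.maf:
            cause[j] = "maf"
    for j in range(m):
        if cause[j]:
            rep.excluded_markers[cause[j]].append(mmap.marker_id[j])
    retained = np.flatnonzero(cause == "")
    return retained, rep


# ---------------------------------------------------------------------------
# Step 3 (post-phasing): relative pruning
# ---------------------------------------------------------------------------


def prune_relatives(pedigree: PedigreeTable, sample_ids, seed: int,
                    family_cap: int = 5, report: QCReport | None = None) -> list:
    """Remove genotyped sires of genotyped sons, then cap half-sib families.

    Per sire, if more than ``family_cap`` genotyped sons remain, retain
    ``family_cap`` chosen uniformly at random under ``seed`` (deterministic).
    Individuals with unknown sire form singleton families and are kept.
    """
    genotyped = list(sample_ids)
    if len(genotyped) != len(set(genotyped)):
        raise PedigreeError("duplicated sample ids passed to prune_relatives")
    genoset = set(genotyped)
    sire_of = pedigree.sire_of()

    fathers = {sire_of[s] for s in genotyped
               if sire_of.get(s) is not None and sire_of[s] in genoset}
    remaining = [s for s in genotyped if s not in fathers]

    families: dict[str, list] = {}
    for s in remaining:
        sire = sire_of.get(s)
        if sire is not None:
            families.setdefault(sire, []).append(s)

    rng = np.random.default_rng(seed)
    dropped: set[str] = set()
    for sire in sorted(families, key=str):
        members = families[sire]
        if len(members) > family_cap:
            keep = set(rng.choice(len(members), size=family_cap, replace=False).tolist())
            for k, s in enumerate(members):
                if k not in keep:
                    dropped.add(s)
    retained = [s for s in remaining if s not in dropped]
    if report is not None:
        pruned = [s for s in genotyped if s not in retained]
        report.excluded_samples["family_pruning"].extend(pruned)
    return retained


def qc_report_frame(rep: QCReport) -> pd.DataFrame:
    rows = []
    for cause, ids in rep.excluded_samples.items():
        rows += [("sample", cause, s) for s in ids]
    for cause, ids in rep.excluded_markers.items():
        rows += [("marker", cause, s) for s in ids]
    return pd.DataFrame(rows, columns=["entity", "cause", "id"])
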