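"""Pipeline orchestration: per-breed scan (cores -> rEHH -> significance),
cross-breed comparison, and the reproducible `run` entry point.

Breed analyses share no state and their outputs are invariant to breed order;
re-running with an identical config and inputs reproduces identical TSVs
(no timestamps are written into outputs).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cores import BlockRule, CoreRegion, core_alleles, find_cores
from .ehh import DOWNSTREAM, UPSTREAM, rehh
from .errors import ConfigError, MissingMarkerError, UndefinedStatisticError
from .io import read_gene_annotation, read_phased_vcf, write_results_tables
from .multibreed import (ProductionGroup, gene_overlap, regions_frame,
                         shared_regions, summarize_regions)
from .significance import annotate_significance
from .types import HaplotypeSet, MarkerMap


@dataclass
class ScanParams:
    min_snps: int = 3
    max_snps: int = 20
    test_distance_cm: float = 0.25
    stop_ehh: float = 0.05
    alpha: float = 0.05
    min_bin_count: int = 10
    tail: str = "upper"
    min_freq: float = 0.25
    block_rule: BlockRule = field(default_factory=BlockRule)

    def validate(self) -> None:
        bad = []
        if not (3 <= self.min_snps <= self.max_snps):
            bad.append("min_snps/max_snps")
        if self.test_distance_cm <= 0:
            bad.append("test_distance_cm")
        if not (0 <= self.stop_ehh < 1):
            bad.append("stop_ehh")
        if not (0 < self.alpha < 1):
            bad.append("alpha")
        if not (0 <= self.min_freq < 1):
            bad.append("min_freq")
        if self.tail not in ("upper", "two-sided"):
            bad.append("tail")
        if bad:
            raise ConfigError(f"invalid scan parameters: {bad}")


def scan_breed(hs: HaplotypeSet, mmap: MarkerMap, params: ScanParams | None = None
               ) -> tuple[pd.DataFrame, list[CoreRegion]]:
    """Core detection plus up/downstream rEHH for every testable core allele.

    Returns the per-allele frame (pre-significance) and the detected regions.
    Alleles skipped for a direction (no marker near the test distance, <2
    carriers or <2 non-carriers) carry NaN there.
    """
    params = params or ScanParams()
    params.validate()
    regions = find_cores(hs, mmap, params.min_snps, params.max_snps, params.block_rule)
    rows = []
    for cid, region in enumerate(regions):
        alleles = core_alleles(region, hs)
        for t, allele in enumerate(alleles):
            rec = {
                "breed": hs.breed,
                "chrom": region.chrom,
                "core_start_bp": region.start_bp,
                "core_end_bp": region.end_bp,
                "n_snps": region.n_snps,
                "core_id": cid,
                "allele_id": f"H{t + 1}",
                "allele": allele.allele,
                "count": allele.count,
                "frequency": allele.frequency,
            }
            for direction, tag in ((UPSTREAM, "up"), (DOWNSTREAM, "down")):
                try:
                    rv = rehh(hs, mmap, alleles, t, direction, params.test_distance_cm)
                    rec[f"ehh_{tag}"] = rv.ehh_t
                    rec[f"rehh_{tag}"] = rv.rehh
                except (MissingMarkerError, UndefinedStatisticError):
                    rec[f"ehh_{tag}"] = np.nan
                    rec[f"rehh_{tag}"] = np.nan
            rows.append(rec)
    columns = ["breed", "chrom", "core_start_bp", "core_end_bp", "n_snps", "core_id",
               "allele_id", "allele", "count", "frequency",
               "ehh_up", "ehh_down", "rehh_up", "rehh_down"]
    return pd.DataFrame(rows, columns=columns), regions


def analyze_breed(hs: HaplotypeSet, mmap: MarkerMap, params: ScanParams | None = None
                  ) -> tuple[pd.DataFrame, list[CoreRegion]]:
    """scan_breed followed by empirical significance annotation."""
    params = params or ScanParams()
    df, regions = scan_breed(hs, mmap, params)
    if len(df) and (np.isfinite(df[["rehh_up", "rehh_down"]].to_numpy(dtype=float)) &
                    (df[["rehh_up", "rehh_down"]].to_numpy(dtype=float) > 0)).any():
        df = annotate_significance(df, params.alpha, params.min_bin_count,
                                   params.tail, params.min_freq)
    else:
        for col in ("p_up", "neg_log10_p_up", "p_down", "neg_log10_p_down"):
            df[col] = np.nan
        for col in ("sig_up", "sig_down", "retained", "significant"):
            df[col] = False
    return df, regions


def significant_regions(df: pd.DataFrame, regions: list[CoreRegion]) -> list[CoreRegion]:
    """Regions with at least one retained, significant core allele."""
    if "significant" not in df.columns or not len(df):
        return []
    ids = sorted(df.loc[df["significant"], "core_id"].unique())
    return [regions[int(i)] for i in ids]


def compare_groups(per_breed: dict[str, tuple[pd.DataFrame, list[CoreRegion]]],
                   groups: list[ProductionGroup], mmap: MarkerMap,
                   annotation=None) -> list:
    """Shared regions across all production groups, ordered deterministically."""
    maps = {b: mmap for b in per_breed}
    out = []
    for group in groups:
        sig = {b: significant_regions(df, regs)
               for b, (df, regs) in per_breed.items() if b in group.breeds}
        out.extend(shared_regions(sig, group, maps))
    if annotation is not None and out:
        out = gene_overlap(out, annotation)
    return out


# ---------------------------------------------------------------------------
# Full configured run
# ---------------------------------------------------------------------------


def validate_run_config(cfg: dict) -> None:
    bad = []
    breeds = cfg.get("breeds")
    if not isinstance(breeds, dict) or not breeds:
        bad.append("breeds")
    else:
        for name, entry in breeds.items():
            if "vcf" not in entry:
                bad.append(f"breeds.{name}.vcf")
            elif not Path(entry["vcf"]).exists():
                bad.append(f"breeds.{name}.vcf (missing file)")
    for g, members in (cfg.get("groups") or {}).items():
        if not isinstance(members, list) or len(members) < 2:
            bad.append(f"groups.{g}")
    qc = cfg.get("qc") or {}
    for key, lo, hi in (("maf", 0, 0.5), ("call_rate", 0, 1),
                        ("mendel_rate", 0, 1), ("max_missing", 0, 1)):
        if key in qc and not (lo <= float(qc[key]) <= hi):
            bad.append(f"qc.{key}")
    if bad:
        raise ConfigError(f"invalid run config fields: {bad}")
    params_from_config(cfg).validate()


def params_from_config(cfg: dict) -> ScanParams:
    p = dict(cfg.get("params") or {})
    rule_keys = {k: p.pop(k) for k in list(p)
                 if k in ("ci_lower_strong", "ci_upper_strong", "ci_upper_recomb", "strong_frac")}
    params = ScanParams(**p)
    if rule_keys:
        params.block_rule = BlockRule(**rule_keys)
    return params


def run_scan(cfg: dict, out_dir) -> dict:
    """Execute the full per-breed + comparison pipeline from a config mapping.

    Config keys: ``breeds`` (name -> {vcf}), ``groups`` (name -> [breeds]),
    ``params`` (ScanParams / block-rule fields), optional ``annotation`` path,
    ``seed``. Writes result TSVs and a JSON manifest into ``out_dir``.
    """
    validate_run_config(cfg)
    params = params_from_config(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    per_breed: dict[str, tuple[pd.DataFrame, list[CoreRegion]]] = {}
    mmap = None
    for breed in sorted(cfg["breeds"]):
        hs, bmap = read_phased_vcf(cfg["breeds"][breed]["vcf"], breed=breed)
        if mmap is None:
            mmap = bmap
        per_breed[breed] = analyze_breed(hs, mmap, params)

    groups = [ProductionGroup(name, list(members))
              for name, members in (cfg.get("groups") or {}).items()]
    annotation = read_gene_annotation(cfg["annotation"]) if cfg.get("annotation") else None
    regions = compare_groups(per_breed, groups, mmap, annotation)

    core_df = pd.concat([df for df, _ in per_breed.values()], ignore_index=True) \
        if per_breed else pd.DataFrame()
    shared_df = regions_frame(regions)
    summary_rows = []
    for breed, (df, regs) in per_breed.items():
        for chrom in dict.fromkeys(str(c) for c in mmap.chrom):
            sub = df[df["chrom"].astype(str) == chrom] if len(df) else df
            summary_rows.append({
                "breed": breed,
                "chrom": chrom,
                "n_cores": int(sub["core_id"].nunique()) if len(sub) else 0,
                "n_core_alleles": int(len(sub)),
                "n_significant": int(sub["significant"].sum()) if len(sub) else 0,
            })
    summary_df = pd.DataFrame(summary_rows)

    paths = write_results_tables(core_df, shared_df, summary_df, out_dir)

    manifest = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "seed": cfg.get("seed"),
        "params": {**{k: v for k, v in asdict(params).items() if k != "block_rule"},
                   "block_rule": asdict(params.block_rule)},
        "outputs": {k: str(v) for k, v in paths.items()},
        "output_sha256": {k: hashlib.sha256(Path(v).read_bytes()).hexdigest()
                          for k, v in paths.items()},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"per_breed": per_breed, "regions": regions, "paths": paths, "manifest": manifest}
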