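"""Readers and writers: PLINK PED/MAP, phased VCF, pedigree TSV, BED/GFF3 genes, result tables.

All tabular outputs are plain TSV with fixed headers so runs can be diffed and
round-tripped. BED input (0-based half-open) is converted to the package-wide
1-based closed convention on read.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DimensionError, ParseError, PhaseError
from .types import MISSING, GeneAnnotation, GenotypeSet, HaplotypeSet, MarkerMap, PedigreeTable

# ---------------------------------------------------------------------------
# PLINK PED/MAP
# ---------------------------------------------------------------------------


def read_map(map_path) -> MarkerMap:
    """Read a PLINK .map (chrom, marker_id, cM, bp); returns the map sorted by (chrom, bp).

    A zero/absent cM column falls back to the default 1 cM/Mb map.
    """
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ParseError(f"{map_path}: line {ln}: expected 4 columns, got {len(parts)}")
            rows.append((parts[0], parts[1], float(parts[2]), int(parts[3])))
    chrom = [r[0] for r in rows]
    mid = [r[1] for r in rows]
    cm = np.array([r[2] for r in rows])
    bp = np.array([r[3] for r in rows], dtype=np.int64)
    pos_cm = cm if np.any(cm != 0) else None
    mm = MarkerMap.from_arrays(mid, chrom, bp, pos_cm)
    mm, _ = mm.sorted()
    return mm


def read_plink(ped_path, map_path) -> tuple[GenotypeSet, MarkerMap]:
    """Read PED/MAP into minor-allele dosages; "0 0" pairs become missing.

    Markers are sorted by (chrom, pos_bp) and genotype columns permuted identically.
    """
    unsorted_map = _read_map_unsorted(map_path)
    n_markers = len(unsorted_map)

    sample_ids, breeds, allele_rows = [], [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6 or (len(parts) - 6) % 2 != 0:
                raise ParseError(f"{ped_path}: line {ln}: ragged PED row ({len(parts)} fields)")
            n_here = (len(parts) - 6) // 2
            if n_here != n_markers:
                raise DimensionError(
                    f"{ped_path}: line {ln}: {n_here} markers in PED vs {n_markers} in MAP"
                )
            breeds.append(parts[0])  # family id doubles as breed label
            sample_ids.append(parts[1])
            allele_rows.append(parts[6:])

    n = len(sample_ids)
    geno = np.full((n, n_markers), MISSING, dtype=np.int8)
    alleles_out = np.empty((n_markers, 2), dtype=object)
    a_mat = np.array(allele_rows, dtype=object).reshape(n, n_markers, 2) if n else np.empty((0, n_markers, 2), dtype=object)

    for m in range(n_markers):
        a1 = a_mat[:, m, 0]
        a2 = a_mat[:, m, 1]
        called = (a1 != "0") & (a2 != "0")
        labels, counts = np.unique(np.concatenate([a1[called], a2[called]]), return_counts=True)
        if len(labels) > 2:
            raise ParseError(
                f"{ped_path}: marker {unsorted_map.marker_id[m]} has >2 alleles: {list(labels)}"
            )
        if len(labels) == 0:
            alleles_out[m] = ("0", "0")
            continue
        if len(labels) == 1:
            major, minor = labels[0], "0"
        else:
            # minor = rarer allele; tie broken toward the lexicographically larger label
            order = np.lexsort((labels, counts))
            if counts[order[0]] == counts[order[1]]:
                major, minor = sorted(labels)
            else:
                minor, major = labels[order[0]], labels[order[1]]
        alleles_out[m] = (major, minor)
        dosage = (a1 == minor).astype(np.int8) + (a2 == minor).astype(np.int8)
        geno[called, m] = dosage[called]

    sorted_map, order = unsorted_map.sorted()
    geno = geno[:, order]
    alleles_out = alleles_out[order]
    gset = GenotypeSet(np.array(sample_ids, dtype=object), np.array(breeds, dtype=object), geno, alleles_out)
    return gset, sorted_map


def _read_map_unsorted(map_path) -> MarkerMap:
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ParseError(f"{map_path}: line {ln}: expected 4 columns, got {len(parts)}")
            rows.append((parts[0], parts[1], float(parts[2]), int(parts[3])))
    cm = np.array([r[2] for r in rows])
    pos_cm = cm if np.any(cm != 0) else None
    return MarkerMap.from_arrays(
        [r[1] for r in rows], [r[0] for r in rows], [r[3] for r in rows], pos_cm
    )


def write_plink(gset: GenotypeSet, mmap: MarkerMap, prefix) -> tuple[Path, Path]:
    """Write PED/MAP; dosages are expanded back to allele labels (A=major, B=minor)."""
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for i in range(len(mmap)):
            fh.write(f"{mmap.chrom[i]}\t{mmap.marker_id[i]}\t{mmap.pos_cm[i]:.6f}\t{mmap.pos_bp[i]}\n")
    alleles = gset.alleles
    if alleles is None:
        alleles = np.array([("A", "B")] * gset.n_markers, dtype=object)
    with open(ped_path, "w") as fh:
        for i in range(gset.n_samples):
            fields = [str(gset.breeds[i]), str(gset.sample_ids[i]), "0", "0", "0", "-9"]
            row = gset.geno[i]
            for m in range(gset.n_markers):
                g = row[m]
                major, minor = alleles[m]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [str(major), str(major)]
                elif g == 1:
                    fields += [str(major), str(minor)]
                else:
                    fields += [str(minor), str(minor)]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# Phased VCF
# ---------------------------------------------------------------------------


def read_phased_vcf(vcf_path, breed: str | None = None, on_invalid: str = "error") -> tuple[HaplotypeSet, MarkerMap]:
    """Read phased biallelic SNPs from a VCF into a 2N x M haplotype matrix.

    ``on_invalid`` controls unphased/multiallelic/missing records:
    ``"error"`` (strict, default) raises; ``"skip"`` drops the record.
    """
    from cyvcf2 import VCF

    if on_invalid not in ("error", "skip"):
        raise ParseError(f"on_invalid must be 'error' or 'skip', got {on_invalid!r}")
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    n = len(samples)
    cols, mids, chroms, pos = [], [], [], []
    for var in vcf:
        label = var.ID or f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            if on_invalid == "skip":
                continue
            raise PhaseError(f"{vcf_path}: {label}: not a biallelic SNP")
        gts = var.genotypes  # [[a0, a1, phased], ...]
        ok = all(len(g) == 3 and g[2] and g[0] >= 0 and g[1] >= 0 for g in gts)
        if not ok:
            if on_invalid == "skip":
                continue
            raise PhaseError(f"{vcf_path}: {label}: unphased or missing genotype")
        col = np.empty(2 * n, dtype=np.uint8)
        for k, g in enumerate(gts):
            col[2 * k] = g[0]
            col[2 * k + 1] = g[1]
        cols.append(col)
        mids.append(label)
        chroms.append(var.CHROM)
        pos.append(var.POS)
    hap = np.stack(cols, axis=1) if cols else np.empty((2 * n, 0), dtype=np.uint8)
    mm = MarkerMap.from_arrays(mids, chroms, pos)
    mm, order = mm.sorted()
    hap = hap[:, order]
    hs = HaplotypeSet(np.array(samples, dtype=object), breed or "unknown", hap)
    return hs, mm


def write_phased_vcf(hs: HaplotypeSet, mmap: MarkerMap, path) -> Path:
    """Write a minimal phased VCF 4.2 (uncompressed text)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(str(c) for c in mmap.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += [str(s) for s in hs.sample_ids]
        fh.write("\t".join(header) + "\n")
        for m in range(len(mmap)):
            gts = [f"{hs.hap[2 * k, m]}|{hs.hap[2 * k + 1, m]}" for k in range(hs.n_samples)]
            row = [str(mmap.chrom[m]), str(mmap.pos_bp[m]), str(mmap.marker_id[m]),
                   "A", "G", ".", "PASS", ".", "GT"] + gts
            fh.write("\t".join(row) + "\n")
    return path


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


def read_pedigree(path) -> PedigreeTable:
    """TSV with columns individual, sire, breed; '0' or empty sire = unknown."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    df["sire"] = df["sire"].replace({"0": None, "": None})
    df["sire"] = df["sire"].where(pd.notna(df["sire"]), None)
    return PedigreeTable(df[["individual", "sire", "breed"]])


def write_pedigree(ped: PedigreeTable, path) -> Path:
    path = Path(path)
    df = ped.table.copy()
    df["sire"] = df["sire"].fillna("0")
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


def read_bed(path) -> GeneAnnotation:
    """BED (0-based half-open) -> 1-based closed gene intervals."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}: line {ln}: BED needs >=3 columns")
            name = parts[3] if len(parts) > 3 else f"feature_{ln}"
            rows.append((name, parts[0], int(parts[1]) + 1, int(parts[2])))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start_bp", "end_bp"])
    return GeneAnnotation(df)


def read_gff3(path, feature_type: str = "gene") -> GeneAnnotation:
    """GFF3 (1-based closed) genes via gffutils (in-memory DB)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type(feature_type, order_by="start"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        rows.append((gid, feat.seqid, feat.start, feat.end))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start_bp", "end_bp"])
    return GeneAnnotation(df)


def read_gene_annotation(path) -> GeneAnnotation:
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        return read_gff3(path)
    return read_bed(path)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

CORE_TABLE_COLUMNS = [
    "breed", "chrom", "core_start_bp", "core_end_bp", "n_snps", "core_id", "allele_id",
    "allele", "count", "frequency", "ehh_up", "ehh_down", "rehh_up", "rehh_down",
    "neg_log10_p_up", "neg_log10_p_down", "retained", "sig_up", "sig_down", "significant",
]

SHARED_TABLE_COLUMNS = [
    "group", "chrom", "start_bp", "end_bp", "breeds", "n_breeds", "core_ids",
    "n_shared_snps", "shared_snps", "genes",
]

SUMMARY_TABLE_COLUMNS = ["breed", "chrom", "n_cores", "n_core_alleles", "n_significant"]


def write_results_tables(core_df: pd.DataFrame, shared_df: pd.DataFrame,
                         summary_df: pd.DataFrame, out_dir) -> dict[str, Path]:
    """Write the three fixed-schema TSVs (per-core-allele, shared regions, per-chromosome summary)."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - env dependent
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    paths = {}

    core = core_df.reindex(columns=CORE_TABLE_COLUMNS) if len(core_df) else pd.DataFrame(columns=CORE_TABLE_COLUMNS)
    paths["core_table"] = out_dir / "core_alleles.tsv"
    core.to_csv(paths["core_table"], sep="\t", index=False)

    shared = shared_df.reindex(columns=SHARED_TABLE_COLUMNS) if len(shared_df) else pd.DataFrame(columns=SHARED_TABLE_COLUMNS)
    paths["shared_table"] = out_dir / "shared_regions.tsv"
    shared.to_csv(paths["shared_table"], sep="\t", index=False)

    summary = summary_df.reindex(columns=SUMMARY_TABLE_COLUMNS) if len(summary_df) else pd.DataFrame(columns=SUMMARY_TABLE_COLUMNS)
    paths["summary_table"] = out_dir / "chromosome_summary.tsv"
    summary.to_csv(paths["summary_table"], sep="\t", index=False)
    return paths


def read_core_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "allele": str, "breed": str})
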