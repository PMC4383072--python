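"""Forward Wright-Fisher simulator: multi-breed phased haplotypes with known
sweeps, sire/half-sib pedigree structure, and QC defects.

Design: discrete generations of random mating with Poisson (Haldane)
recombination over the marker map; standing variation only (initial allele
frequencies ~ Uniform(0.05, 0.95), no new mutations); additive fitness
(1, 1+s, 1+2s) at a selected site carried as a hidden extra column during the
sweep phase. Every generator is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, SweepFailureError
from .types import MISSING, GenotypeSet, HaplotypeSet, MarkerMap, PedigreeTable


@dataclass
class SweepSpec:
    chrom: str
    pos_bp: int
    s: float
    target_freq: tuple[float, float] = (0.5, 0.8)
    groups: list[str] = field(default_factory=list)   # production groups receiving it
    breeds: list[str] = field(default_factory=list)   # explicit breed assignment
    # If set, the variant arises in the shared ancestral population and is
    # selected to this frequency window BEFORE the breed split; member breeds
    # then continue selecting the same haplotype up to target_freq. This makes
    # a "shared" sweep a single ancestral variant rather than parallel new
    # mutations.
    origin_freq: tuple[float, float] | None = None


@dataclass
class BreedSpec:
    name: str
    n_diploids: int
    groups: list[str] = field(default_factory=list)


@dataclass
class PedigreeSpec:
    n_sires: int = 0
    sons_per_sire: int = 0


@dataclass
class DegradationSpec:
    missing_rate: float = 0.0
    error_rate: float = 0.0
    n_replicates: int = 0


@dataclass
class SimulationConfig:
    n_diploids: int = 100
    n_chromosomes: int = 1
    chrom_length_bp: int = 50_000_000
    markers_per_mb: float = 20.0
    recomb_cm_per_mb: float = 1.0
    generations: int = 100
    divergence_generations: int = 50
    sweeps: list[SweepSpec] = field(default_factory=list)
    breeds: list[BreedSpec] = field(default_factory=list)
    pedigree: PedigreeSpec = field(default_factory=PedigreeSpec)
    degradation: DegradationSpec = field(default_factory=DegradationSpec)
    seed: int = 0
    sweep_max_generations: int = 2000
    sweep_max_retries: int = 300

    def validate(self) -> None:
        bad = []
        if self.n_diploids < 2:
            bad.append("n_diploids")
        if self.n_chromosomes < 1:
            bad.append("n_chromosomes")
        if self.chrom_length_bp < 1:
            bad.append("chrom_length_bp")
        if self.markers_per_mb <= 0:
            bad.append("markers_per_mb")
        if self.recomb_cm_per_mb < 0:
            bad.append("recomb_cm_per_mb")
        if self.generations < 0:
            bad.append("generations")
        for k, spec in enumerate(self.sweeps):
            lo, hi = spec.target_freq
            if not (0 < lo < hi < 1):
                bad.append(f"sweeps[{k}].target_freq")
            if spec.s < 0:
                bad.append(f"sweeps[{k}].s")
        dg = self.degradation
        for name in ("missing_rate", "error_rate"):
            if not (0 <= getattr(dg, name) <= 1):
                bad.append(f"degradation.{name}")
        if bad:
            raise ConfigError(f"invalid simulation config fields: {bad}")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["sweeps"] = [SweepSpec(**{**s, "target_freq": tuple(s.get("target_freq", (0.5, 0.8)))})
                       for s in d.get("sweeps", [])]
        d["breeds"] = [BreedSpec(**b) for b in d.get("breeds", [])]
        if "pedigree" in d:
            d["pedigree"] = PedigreeSpec(**d["pedigree"])
        if "degradation" in d:
            d["degradation"] = DegradationSpec(**d["degradation"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Map and base population
# ---------------------------------------------------------------------------


def build_map(config: SimulationConfig) -> MarkerMap:
    """Evenly spaced markers at the configured density; default 1 cM/Mb map."""
    per_chrom = max(2, int(round(config.markers_per_mb * config.chrom_length_bp / 1e6)))
    spacing = config.chrom_length_bp // per_chrom
    mids, chroms, pos = [], [], []
    for c in range(1, config.n_chromosomes + 1):
        for i in range(per_chrom):
            mids.append(f"snp{c}_{i}")
            chroms.append(str(c))
            pos.append(spacing // 2 + i * spacing + 1)
    bp = np.array(pos, dtype=np.int64)
    cm = bp * 1e-6 * config.recomb_cm_per_mb
    return MarkerMap.from_arrays(mids, chroms, bp, cm)


def _switch_probs(mmap: MarkerMap, recomb_cm_per_mb: float) -> np.ndarray:
    """Per-marker probability that a gamete switches source haplotype before
    this marker. Chromosome starts get 0.5 (independent assortment)."""
    m = len(mmap)
    probs = np.empty(m)
    for lo, hi in mmap.chrom_slices().values():
        probs[lo] = 0.5
        if hi - lo > 1:
            d_cm = np.diff(mmap.pos_cm[lo:hi])
            d_morgan = d_cm / 100.0
            probs[lo + 1 : hi] = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))  # Haldane
    if m:
        probs[0] = 0.5
    return probs


def _wf_generation(H: np.ndarray, switch_p: np.ndarray, rng: np.random.Generator,
                   parent_weights: np.ndarray | None = None) -> np.ndarray:
    """One generation of random mating with recombination.

    Each of N children receives two independent recombinant gametes from
    parents sampled (with replacement) proportionally to ``parent_weights``.
    """
    n_hap, m = H.shape
    n = n_hap // 2
    if parent_weights is not None:
        w = parent_weights / parent_weights.sum()
        parents = rng.choice(n, size=n_hap, p=w)
    else:
        parents = rng.integers(0, n, size=n_hap)
    switches = rng.random((n_hap, m)) < switch_p[None, :]
    chooser = np.cumsum(switches, axis=1) & 1
    rows = 2 * parents[:, None] + chooser
    return H[rows, np.arange(m)[None, :]]


def simulate_base_population(config: SimulationConfig,
                             rng: np.random.Generator | None = None) -> tuple[HaplotypeSet, MarkerMap]:
    """Initial haplotypes from Uniform(0.05, 0.95) allele frequencies, then
    ``config.generations`` generations of neutral Wright-Fisher mating."""
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    mmap = build_map(config)
    m = len(mmap)
    freqs = rng.uniform(0.05, 0.95, size=m)
    H = (rng.random((2 * config.n_diploids, m)) < freqs[None, :]).astype(np.uint8)
    switch_p = _switch_probs(mmap, config.recomb_cm_per_mb)
    for _ in range(config.generations):
        H = _wf_generation(H, switch_p, rng)
    ids = np.array([f"ind{i}" for i in range(config.n_diploids)], dtype=object)
    return HaplotypeSet(ids, "base", H), mmap


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------


def _extended_map(mmap: MarkerMap, sweeps: list[SweepSpec], recomb_cm_per_mb: float
                  ) -> tuple[MarkerMap, list[int]]:
    """Splice one hidden selected-site column per sweep into the map.

    Returns the extended map and the column index of each sweep's site.
    """
    slices = mmap.chrom_slices()
    for spec in sweeps:
        if str(spec.chrom) not in slices:
            raise ConfigError(f"sweep chromosome {spec.chrom!r} not on map")
    order = sorted(range(len(sweeps)),
                   key=lambda j: (_chrom_key(sweeps[j].chrom), sweeps[j].pos_bp))
    bp = list(mmap.pos_bp)
    cm = list(mmap.pos_cm)
    chrom = list(mmap.chrom)
    mid = list(mmap.marker_id)
    positions = [0] * len(sweeps)
    for j in order:
        spec = sweeps[j]
        ext = MarkerMap.from_arrays(mid, chrom, bp, cm)
        lo, hi = ext.chrom_slices()[str(spec.chrom)]
        at = lo + int(np.searchsorted(np.array(bp[lo:hi]), spec.pos_bp))
        bp.insert(at, spec.pos_bp)
        cm.insert(at, spec.pos_bp * 1e-6 * recomb_cm_per_mb)
        chrom.insert(at, str(spec.chrom))
        mid.insert(at, f"__selected_{j}__")
    ext_map = MarkerMap.from_arrays(mid, chrom, bp, cm)
    for j in range(len(sweeps)):
        positions[j] = mid.index(f"__selected_{j}__")
    return ext_map, positions


def _chrom_key(label):
    from .types import _chrom_sort_key

    return _chrom_sort_key(label)


def _select_until(H: np.ndarray, col: int, switch_p: np.ndarray, s: float,
                  window: tuple[float, float], rng: np.random.Generator,
                  max_generations: int) -> tuple[np.ndarray, float, int, str]:
    """Run fitness-weighted generations until the allele at ``col`` enters the
    window. Status is 'hit', 'lost' or 'timeout'."""
    lo_f, hi_f = window
    gens = 0
    while gens < max_generations:
        sel = H[:, col]
        freq = sel.mean()
        if freq == 0:
            return H, 0.0, gens, "lost"
        if lo_f < freq < hi_f:
            return H, float(freq), gens, "hit"
        geno = sel[0::2].astype(np.int64) + sel[1::2].astype(np.int64)
        H = _wf_generation(H, switch_p, rng, parent_weights=1.0 + s * geno)
        gens += 1
    return H, float(H[:, col].mean()), gens, "timeout"


def implant_sweep(hs: HaplotypeSet, mmap: MarkerMap, spec: SweepSpec, seed: int,
                  recomb_cm_per_mb: float = 1.0, max_generations: int = 2000,
                  max_retries: int = 300) -> tuple[HaplotypeSet, float, int]:
    """Place a new derived allele on one random haplotype and run forward
    selection (fitness 1 / 1+s / 1+2s) until its frequency enters the target
    window. Runs losing the allele restart with a new seed offset; exhausting
    the retry budget raises SweepFailureError.

    Returns (population at stopping time, achieved frequency, generations run).
    """
    if spec.s < 0:
        raise ConfigError("selection coefficient must be >= 0")
    ext_map, (insert_at,) = _extended_map(mmap, [spec], recomb_cm_per_mb)
    switch_p = _switch_probs(ext_map, recomb_cm_per_mb)
    n_hap = hs.n_haplotypes
    base = np.insert(hs.hap, insert_at, 0, axis=1)

    for attempt in range(max_retries):
        rng = np.random.default_rng([seed, attempt])
        H = base.copy()
        H[rng.integers(0, n_hap), insert_at] = 1
        H, freq, gens, status = _select_until(
            H, insert_at, switch_p, spec.s, spec.target_freq, rng, max_generations)
        if status == "hit":
            out = np.delete(H, insert_at, axis=1)
            return (HaplotypeSet(hs.sample_ids.copy(), hs.breed, out), freq, gens)
    raise SweepFailureError(
        f"sweep at {spec.chrom}:{spec.pos_bp} failed after {max_retries} attempts"
    )


# ---------------------------------------------------------------------------
# Breeds
# ---------------------------------------------------------------------------


def simulate_breeds(config: SimulationConfig) -> tuple[dict[str, HaplotypeSet], MarkerMap, pd.DataFrame]:
    """Base population split into breeds, evolved independently, with group- or
    breed-assigned sweeps implanted at the same map position in each member.

    Returns per-breed HaplotypeSets, the shared map, and a truth table
    (breed, group, chrom, pos_bp, s, achieved_freq) for power evaluation.
    """
    config.validate()
    if len(config.breeds) < 2:
        raise ConfigError("simulate_breeds needs >= 2 breeds")
    base, mmap = simulate_base_population(config)

    # every sweep's selected site travels as a hidden column from here on
    ext_map, site_cols = _extended_map(mmap, config.sweeps, config.recomb_cm_per_mb)
    switch_p = _switch_probs(ext_map, config.recomb_cm_per_mb)
    H_base = base.hap
    for col in sorted(site_cols):
        H_base = np.insert(H_base, col, 0, axis=1)

    # ancestral (pre-split) phase for sweeps with an origin window: the variant
    # arises once and is selected into its origin frequency range
    for j, sweep in enumerate(config.sweeps):
        if sweep.origin_freq is None:
            continue
        placed = False
        for attempt in range(config.sweep_max_retries):
            rng = np.random.default_rng([config.seed, 5000 + j, attempt])
            H_try = H_base.copy()
            H_try[rng.integers(0, H_try.shape[0]), site_cols[j]] = 1
            H_try, freq, _, status = _select_until(
                H_try, site_cols[j], switch_p, sweep.s, sweep.origin_freq,
                rng, config.sweep_max_generations)
            if status == "hit":
                H_base = H_try
                placed = True
                break
        if not placed:
            raise SweepFailureError(
                f"ancestral sweep at {sweep.chrom}:{sweep.pos_bp} failed to reach "
                f"{sweep.origin_freq} after {config.sweep_max_retries} attempts")

    out: dict[str, HaplotypeSet] = {}
    truth_rows = []
    # breeds partition the founders when sizes allow (a split, not a bottleneck);
    # oversubscribed configs fall back to sampling with replacement
    n_base = H_base.shape[0] // 2
    total = sum(b.n_diploids for b in config.breeds)
    split_rng = np.random.default_rng([config.seed, 999])
    partition = split_rng.permutation(n_base) if total <= n_base else None
    offset = 0
    for k, bspec in enumerate(config.breeds):
        if partition is not None:
            pick0 = partition[offset : offset + bspec.n_diploids]
            offset += bspec.n_diploids
        else:
            pick0 = None
        applicable = [(j, sw) for j, sw in enumerate(config.sweeps)
                      if bspec.name in sw.breeds or any(g in bspec.groups for g in sw.groups)]

        # the whole breed-formation phase (divergence + sweeps) retries on
        # sweep loss: a breed in which an inherited variant drifted out is
        # re-formed with a fresh stream
        breed_rows = None
        for breed_attempt in range(config.sweep_max_retries):
            rng = np.random.default_rng([config.seed, 1000 + k, breed_attempt])
            pick = pick0 if pick0 is not None else rng.choice(
                n_base, size=bspec.n_diploids, replace=True)
            rows = np.empty(2 * bspec.n_diploids, dtype=np.int64)
            rows[0::2] = 2 * pick
            rows[1::2] = 2 * pick + 1
            H = H_base[rows].copy()
            for _ in range(config.divergence_generations):
                H = _wf_generation(H, switch_p, rng)

            rows_here = []
            failed = False
            for j, sweep in applicable:
                if sweep.origin_freq is not None:
                    H, freq, _, status = _select_until(
                        H, site_cols[j], switch_p, sweep.s, sweep.target_freq,
                        rng, config.sweep_max_generations)
                    if status != "hit":
                        failed = True
                        break
                else:
                    freq = None
                    for attempt in range(config.sweep_max_retries):
                        rng_s = np.random.default_rng(
                            [config.seed, 2000 + k, j, breed_attempt, attempt])
                        H_try = H.copy()
                        H_try[rng_s.integers(0, H_try.shape[0]), site_cols[j]] = 1
                        H_try, f, _, status = _select_until(
                            H_try, site_cols[j], switch_p, sweep.s, sweep.target_freq,
                            rng_s, config.sweep_max_generations)
                        if status == "hit":
                            H, freq = H_try, f
                            break
                    if freq is None:
                        failed = True
                        break
                rows_here.append({
                    "breed": bspec.name,
                    "group": ",".join(sweep.groups) if sweep.groups else "",
                    "chrom": sweep.chrom,
                    "pos_bp": sweep.pos_bp,
                    "s": sweep.s,
                    "achieved_freq": freq,
                })
            if not failed:
                breed_rows = rows_here
                break
        if breed_rows is None:
            raise SweepFailureError(
                f"breed {bspec.name}: sweeps failed after "
                f"{config.sweep_max_retries} formation attempts")
        truth_rows.extend(breed_rows)

        H_out = np.delete(H, sorted(site_cols), axis=1)
        ids = np.array([f"{bspec.name}_{i}" for i in range(bspec.n_diploids)], dtype=object)
        out[bspec.name] = HaplotypeSet(ids, bspec.name, H_out)
    truth = pd.DataFrame(truth_rows,
                         columns=["breed", "group", "chrom", "pos_bp", "s", "achieved_freq"])
    return out, mmap, truth


# ---------------------------------------------------------------------------
# Degradation and pedigree structure
# ---------------------------------------------------------------------------


def degrade_and_pedigree(hs: HaplotypeSet, mmap: MarkerMap, config: SimulationConfig,
                         seed: int | None = None
                         ) -> tuple[GenotypeSet, PedigreeTable, list[tuple[str, str]]]:
    """Collapse haplotypes to genotypes and add the QC test surface: Mendelian-
    consistent sire/son duos, half-sib families, replicate samples, missing
    cells, and genotype errors. Returns (genotypes, pedigree, replicate pairs).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ped_spec = config.pedigree
    dg = config.degradation
    n = hs.n_samples
    if ped_spec.n_sires > n:
        raise ConfigError("more sires requested than individuals in the population")

    switch_p = _switch_probs(mmap, config.recomb_cm_per_mb)
    m = hs.n_markers
    geno_rows = [hs.hap[2 * k].astype(np.int8) + hs.hap[2 * k + 1].astype(np.int8)
                 for k in range(n)]
    ids = [str(s) for s in hs.sample_ids]
    sires: list[str | None] = [None] * n

    sire_idx = rng.choice(n, size=ped_spec.n_sires, replace=False) if ped_spec.n_sires else np.array([], dtype=int)
    for si in sire_idx:
        for j in range(ped_spec.sons_per_sire):
            son_id = f"{ids[si]}_son{j}"

            def gamete(k: int) -> np.ndarray:
                switches = rng.random(m) < switch_p
                chooser = np.cumsum(switches) & 1
                return np.where(chooser == 0, hs.hap[2 * k], hs.hap[2 * k + 1])

            other = int(rng.integers(0, n))
            geno_rows.append((gamete(si).astype(np.int8) + gamete(other).astype(np.int8)))
            ids.append(son_id)
            sires.append(ids[si])

    replicate_pairs: list[tuple[str, str]] = []
    if dg.n_replicates:
        rep_idx = rng.choice(n, size=min(dg.n_replicates, n), replace=False)
        for ri in rep_idx:
            rep_id = f"{ids[ri]}_rep"
            geno_rows.append(geno_rows[ri].copy())
            ids.append(rep_id)
            sires.append(sires[ri])
            replicate_pairs.append((ids[ri], rep_id))

    geno = np.stack(geno_rows)
    if dg.error_rate > 0:
        err = rng.random(geno.shape) < dg.error_rate
        shift = rng.integers(1, 3, size=geno.shape)
        geno = np.where(err, (geno + shift) % 3, geno).astype(np.int8)
    if dg.missing_rate > 0:
        miss = rng.random(geno.shape) < dg.missing_rate
        geno = np.where(miss, MISSING, geno).astype(np.int8)

    breeds = np.full(len(ids), hs.breed, dtype=object)
    gset = GenotypeSet(np.array(ids, dtype=object), breeds, geno)
    ped = PedigreeTable(pd.DataFrame({
        "individual": ids,
        "sire": [s if s is not None else None for s in sires],
        "breed": [hs.breed] * len(ids),
    }))
    return gset, ped, replicate_pairs
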