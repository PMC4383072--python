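import numpy as np
import pandas as pd
import pytest

from rehhscan.errors import ConfigError, SweepFailureError
from rehhscan.ld import haplotype_r2
from rehhscan.qc import prune_relatives
from rehhscan.simulate import (BreedSpec, DegradationSpec, PedigreeSpec,
                               SimulationConfig, SweepSpec, degrade_and_pedigree,
                               implant_sweep, simulate_base_population,
                               simulate_breeds)
from rehhscan.types import MISSING


def small_cfg(**kw):
    defaults = dict(n_diploids=50, chrom_length_bp=5_000_000, markers_per_mb=20,
                    generations=20, seed=1)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestBasePopulation:
    def test_deterministic_under_seed(self):
        hs1, mm1 = simulate_base_population(small_cfg())
        hs2, mm2 = simulate_base_population(small_cfg())
        assert np.array_equal(hs1.hap, hs2.hap)
        assert np.array_equal(mm1.pos_bp, mm2.pos_bp)

    def test_different_seed_differs(self):
        hs1, _ = simulate_base_population(small_cfg(seed=1))
        hs2, _ = simulate_base_population(small_cfg(seed=2))
        assert not np.array_equal(hs1.hap, hs2.hap)

    def test_invalid_config_lists_fields(self):
        cfg = small_cfg(n_diploids=1, markers_per_mb=-1)
        with pytest.raises(ConfigError, match="n_diploids"):
            simulate_base_population(cfg)

    def test_zero_generations_columns_independent(self):
        """Mean inter-marker r2 under independence ~ 1/(2N); allow a 3 s.e. band."""
        cfg = small_cfg(n_diploids=100, generations=0, chrom_length_bp=5_000_000, seed=5)
        hs, mm = simulate_base_population(cfg)
        H = hs.hap
        p = H.mean(axis=0)
        poly = np.flatnonzero((p > 0) & (p < 1))
        r2s = []
        for k in range(len(poly) - 1):
            i, j = poly[k], poly[k + 1]
            r2s.append(haplotype_r2(H[:, i], H[:, j]))
        # E[r2] ~= 1/n_hap for independent loci; sd of mean ~ sqrt(2)/n/sqrt(k)
        n_hap = H.shape[0]
        bound = 1 / n_hap + 3 * (2 / n_hap) / np.sqrt(len(r2s))
        assert np.mean(r2s) < bound

    def test_no_recombination_blocks_do_not_increase(self):
        cfg = small_cfg(recomb_cm_per_mb=0.0, generations=0, seed=9)
        hs, mm = simulate_base_population(cfg)
        from rehhscan.simulate import _switch_probs, _wf_generation

        switch = _switch_probs(mm, 0.0)
        assert np.all(switch[1:] == 0)
        H = hs.hap
        rng = np.random.default_rng(0)

        def n_distinct(H):
            return len({tuple(row) for row in H})

        counts = [n_distinct(H)]
        for _ in range(15):
            H = _wf_generation(H, switch, rng)
            counts.append(n_distinct(H))
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_neutral_frequencies_are_a_martingale(self):
        """Mean drift of marker frequencies over generations ~ 0 (3 s.e. band)."""
        drifts = []
        for seed in range(25):
            cfg = small_cfg(n_diploids=60, generations=0, chrom_length_bp=2_500_000, seed=seed)
            hs, mm = simulate_base_population(cfg)
            from rehhscan.simulate import _switch_probs, _wf_generation

            switch = _switch_probs(mm, 1.0)
            H0 = hs.hap
            H = H0.copy()
            rng = np.random.default_rng(seed + 1000)
            for _ in range(10):
                H = _wf_generation(H, switch, rng)
            drifts.extend(H.mean(axis=0) - H0.mean(axis=0))
        drifts = np.asarray(drifts)
        se = drifts.std(ddof=1) / np.sqrt(len(drifts))
        assert abs(drifts.mean()) < 3 * se


class TestImplantSweep:
    def test_stops_inside_target_window(self):
        hs, mm = simulate_base_population(small_cfg(n_diploids=100, seed=2))
        spec = SweepSpec("1", 2_500_000, s=0.05, target_freq=(0.5, 0.8))
        out, freq, gens = implant_sweep(hs, mm, spec, seed=7)
        assert 0.5 < freq < 0.8
        assert out.hap.shape == hs.hap.shape

    def test_neutral_sweep_to_fixation_fails(self):
        hs, mm = simulate_base_population(small_cfg(n_diploids=30, seed=3))
        spec = SweepSpec("1", 2_500_000, s=0.0, target_freq=(0.985, 0.995))
        with pytest.raises(SweepFailureError, match="attempts"):
            implant_sweep(hs, mm, spec, seed=11, max_generations=30, max_retries=3)

    def test_deterministic(self):
        hs, mm = simulate_base_population(small_cfg(n_diploids=80, seed=4))
        spec = SweepSpec("1", 2_500_000, s=0.1)
        a, fa, _ = implant_sweep(hs, mm, spec, seed=5)
        b, fb, _ = implant_sweep(hs, mm, spec, seed=5)
        assert fa == fb
        assert np.array_equal(a.hap, b.hap)

    def test_sweep_elevates_ehh_vs_matched_neutral(self):
        """Swept populations carry longer frequent haplotypes than neutral ones
        at the sweep position (majority of seed pairs)."""
        from rehhscan.cores import CoreRegion, core_alleles
        from rehhscan.ehh import DOWNSTREAM, ehh_at

        def mean_major_ehh(hs, mm, pos, window_markers=10):
            center = int(np.argmin(np.abs(mm.pos_bp - pos)))
            region = CoreRegion("1", center, center,
                                int(mm.pos_bp[center]), int(mm.pos_bp[center]))
            alleles = core_alleles(region, hs)
            a = alleles[0]
            cols = np.arange(center + 1, min(center + 1 + window_markers, len(mm)))
            return ehh_at(hs.hap[np.ix_(a.carrier_rows, cols)])

        wins = 0
        n_pairs = 10
        for seed in range(n_pairs):
            cfg = SimulationConfig(n_diploids=100, chrom_length_bp=10_000_000,
                                   markers_per_mb=20, generations=60, seed=seed)
            neutral, mm = simulate_base_population(cfg)
            spec = SweepSpec("1", 5_000_000, s=0.1, target_freq=(0.5, 0.8))
            swept, freq, _ = implant_sweep(neutral, mm, spec, seed=seed + 500)
            wins += mean_major_ehh(swept, mm, 5_000_000) > mean_major_ehh(neutral, mm, 5_000_000)
        assert wins >= 0.6 * n_pairs


class TestSimulateBreeds:
    def cfg(self, sweeps):
        return small_cfg(
            n_diploids=60, divergence_generations=5, sweeps=sweeps,
            breeds=[BreedSpec("D1", 30, ["dairy"]), BreedSpec("D2", 30, ["dairy"]),
                    BreedSpec("B1", 30, ["beef"]), BreedSpec("B2", 30, ["beef"]),
                    BreedSpec("DP", 30, ["dairy", "beef"])],
        )

    def test_group_sweep_truth_rows(self):
        sweeps = [SweepSpec("1", 2_500_000, s=0.3, groups=["dairy"])]
        breeds, mm, truth = simulate_breeds(self.cfg(sweeps))
        assert set(truth.breed) == {"D1", "D2", "DP"}
        assert (truth.pos_bp == 2_500_000).all()
        for f in truth.achieved_freq:
            assert 0.5 < f < 0.8

    def test_no_sweeps_empty_truth(self):
        breeds, mm, truth = simulate_breeds(self.cfg([]))
        assert truth.empty
        assert len(breeds) == 5

    def test_dual_purpose_breed_gets_both_group_sweeps(self):
        sweeps = [SweepSpec("1", 1_500_000, s=0.3, groups=["dairy"]),
                  SweepSpec("1", 4_000_000, s=0.3, groups=["beef"])]
        _, _, truth = simulate_breeds(self.cfg(sweeps))
        dp = truth[truth.breed == "DP"]
        assert sorted(dp.pos_bp) == [1_500_000, 4_000_000]

    def test_breeds_diverge(self):
        breeds, _, _ = simulate_breeds(self.cfg([]))
        assert not np.array_equal(breeds["D1"].hap, breeds["D2"].hap)


class TestDegradeAndPedigree:
    def cfg(self, **kw):
        base = dict(pedigree=PedigreeSpec(n_sires=2, sons_per_sire=3),
                    degradation=DegradationSpec(missing_rate=0.0, error_rate=0.0,
                                                n_replicates=2))
        base.update(kw)
        return small_cfg(n_diploids=40, **base)

    def setup_pop(self, cfg):
        hs, mm = simulate_base_population(cfg)
        return hs, mm

    def test_zero_error_rate_means_no_mendelian_errors(self):
        from rehhscan.qc import mendelian_error_rate

        cfg = self.cfg()
        hs, mm = self.setup_pop(cfg)
        gset, ped, reps = degrade_and_pedigree(hs, mm, cfg)
        idx = {s: i for i, s in enumerate(gset.sample_ids)}
        checked = 0
        for r in ped.table.itertuples():
            if r.sire is not None and r.sire in idx and r.individual in idx:
                rate = mendelian_error_rate(gset.geno[idx[r.sire]], gset.geno[idx[r.individual]])
                assert rate == 0.0
                checked += 1
        assert checked == 6

    def test_missing_rate_within_band(self):
        cfg = self.cfg(degradation=DegradationSpec(missing_rate=0.05))
        hs, mm = self.setup_pop(cfg)
        gset, _, _ = degrade_and_pedigree(hs, mm, cfg)
        frac = (gset.geno == MISSING).mean()
        n = gset.geno.size
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < 3 * se

    def test_replicates_identical_without_degradation(self):
        cfg = self.cfg()
        hs, mm = self.setup_pop(cfg)
        gset, _, reps = degrade_and_pedigree(hs, mm, cfg)
        assert len(reps) == 2
        idx = {s: i for i, s in enumerate(gset.sample_ids)}
        for a, b in reps:
            assert np.array_equal(gset.geno[idx[a]], gset.geno[idx[b]])

    def test_one_sire_ten_sons_composes_with_pruning(self):
        cfg = self.cfg(pedigree=PedigreeSpec(n_sires=1, sons_per_sire=10),
                       degradation=DegradationSpec())
        hs, mm = self.setup_pop(cfg)
        gset, ped, _ = degrade_and_pedigree(hs, mm, cfg)
        sire_id = ped.table.loc[ped.table.sire.notna(), "sire"].iloc[0]
        sons = ped.table.loc[ped.table.sire.notna(), "individual"].tolist()
        kept = prune_relatives(ped, [sire_id] + sons, seed=0)
        assert sire_id not in kept
        assert len(kept) == 5
        assert set(kept) <= set(sons)

    def test_too_many_sires_rejected(self):
        cfg = self.cfg(pedigree=PedigreeSpec(n_sires=100, sons_per_sire=1))
        hs, mm = self.setup_pop(cfg)
        with pytest.raises(ConfigError):
            degrade_and_pedigree(hs, mm, cfg)

    def test_deterministic(self):
        cfg = self.cfg(degradation=DegradationSpec(missing_rate=0.02, error_rate=0.01,
                                                   n_replicates=1))
        hs, mm = self.setup_pop(cfg)
        g1, p1, r1 = degrade_and_pedigree(hs, mm, cfg, seed=77)
        g2, p2, r2 = degrade_and_pedigree(hs, mm, cfg, seed=77)
        assert np.array_equal(g1.geno, g2.geno)
        assert r1 == r2
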