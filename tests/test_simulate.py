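import numpy as np
import pytest

from goshift.ld import r_squared
from goshift.simulate import (
    CausalProportionEstimator,
    Colocalization,
    ConfigError,
    SimConfig,
    simulate_genome,
    delta_for_set,
    draw_functional_set,
    loci_for_rows,
    power_study,
)


def tiny_config(**kw):
    base = dict(
        n_chromosomes=4,
        chrom_length=1_000_000,
        n_variants=2_000,
        ld_block_length=20_000,
        seed=11,
    )
    base.update(kw)
    return SimConfig(**base)


class TestSimulateGenome:
    def test_zero_density_gives_empty_track(self):
        g = simulate_genome(tiny_config(annotation_density=0.0))
        assert len(g.tracks["X"]) == 0

    def test_seed_reproducibility(self):
        a = simulate_genome(tiny_config())
        b = simulate_genome(tiny_config())
        assert (a.positions == b.positions).all()
        assert (a.haplotypes == b.haplotypes).all()
        assert [(iv.chrom, iv.start, iv.end) for iv in a.tracks["X"]] == [
            (iv.chrom, iv.start, iv.end) for iv in b.tracks["X"]
        ]

    def test_realized_coverage_near_target(self, small_genome):
        cfg = small_genome.config
        covered = sum(len(iv) for iv in small_genome.tracks["X"].intervals)
        target = cfg.annotation_density * cfg.genome_length
        assert abs(covered - target) <= 0.1 * target

    def test_within_block_r2_reaches_target(self, small_genome):
        g = small_genome
        r2s = []
        for b in np.unique(g.blocks)[:30]:
            rows = g.block_rows(b)
            if len(rows) < 2:
                continue
            r2 = g.block_r2(b)
            iu = np.triu_indices(len(rows), k=1)
            r2s.extend(r2[iu].tolist())
        assert np.mean(r2s) >= g.config.within_block_r2 - 0.05

    def test_mafs_respect_floor(self, small_genome):
        assert (small_genome.mafs >= small_genome.config.maf_min).all()
        assert (small_genome.mafs <= 0.5).all()

    def test_infeasible_config_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(annotation_density=1.5)
        with pytest.raises(ConfigError):
            SimConfig(annotation_median_size=10_000_000)

    def test_colocalized_track_overlaps_x(self):
        g = simulate_genome(
            tiny_config(colocalization=Colocalization(prob=1.0, jitter=200, size_factor=1.0))
        )
        x_cov = sum(len(iv) for iv in g.tracks["X"].intervals)
        # count X bases also covered by Y: most X intervals have a jittered partner
        y = g.tracks["Y"].by_chrom()
        shared = 0
        for iv in g.tracks["X"]:
            if iv.chrom not in y:
                continue
            starts, ends = y[iv.chrom]
            lo = np.searchsorted(ends, iv.start, side="right")
            hi = np.searchsorted(starts, iv.end, side="left")
            for k in range(lo, hi):
                shared += min(iv.end, ends[k]) - max(iv.start, starts[k])
        assert shared / x_cov > 0.3


class TestProxies:
    def test_proxy_r2_above_threshold(self, small_genome):
        g = small_genome
        thr = g.config.proxy_r2_threshold
        rng = np.random.default_rng(0)
        for i in rng.integers(0, g.n_variants, size=20):
            rows = g.proxy_rows(int(i))
            assert int(i) in rows
            for j in rows:
                if j == i:
                    continue
                r2 = r_squared(g.haplotypes[int(i)], g.haplotypes[int(j)])
                assert r2 > thr

    def test_ld_counts_consistent_with_proxy_positions(self, small_genome):
        g = small_genome
        counts = g.ld_counts()
        pos = g.proxy_positions()
        assert all(counts[i] == len(pos[i]) - 1 for i in range(0, g.n_variants, 97))


class TestDrawFunctionalSet:
    def test_full_causal_fraction_inside_annotation(self, small_genome):
        fs = draw_functional_set(small_genome, "X", 12, 1.0, seed=1)
        assert len(fs.index_rows) == 12
        assert fs.truth.causal_in_category.all()
        flags = small_genome.in_track("X")[fs.truth.causal_row.to_numpy()]
        assert flags.all()

    def test_zero_causal_fraction_outside_annotation(self, small_genome):
        fs = draw_functional_set(small_genome, "X", 12, 0.0, seed=2)
        assert not fs.truth.causal_in_category.any()

    def test_mixed_fraction_truth_audit(self, small_genome):
        fs = draw_functional_set(small_genome, "X", 20, 0.5, seed=3)
        assert int(fs.truth.causal_in_category.sum()) == 10

    def test_spacing_filter_enforced(self, small_genome):
        fs = draw_functional_set(small_genome, "X", 15, 0.5, seed=4)
        chroms = small_genome.chroms[fs.index_rows]
        pos = small_genome.positions[fs.index_rows]
        for c in np.unique(chroms):
            p = np.sort(pos[chroms == c])
            assert (np.diff(p) >= small_genome.config.min_spacing).all()

    def test_tags_are_linked_to_causal(self, small_genome):
        g = small_genome
        fs = draw_functional_set(g, "X", 10, 1.0, seed=5)
        for row in fs.truth.itertuples():
            if row.index_row == row.causal_row:
                continue
            r2 = r_squared(g.haplotypes[row.causal_row], g.haplotypes[row.index_row])
            assert r2 >= g.config.tag_r2_min

    def test_genome_too_small_for_spacing(self, small_genome):
        with pytest.raises(ConfigError, match="too small"):
            draw_functional_set(small_genome, "X", 1_000, 1.0, seed=6)


class TestStudies:
    def test_power_monotone_and_calibrated_smoke(self, small_genome):
        df = power_study(
            small_genome,
            [0.0, 1.0],
            n_sets=20,
            n_iterations=200,
            alpha_levels=(0.05,),
            n_loci=20,
            seed=7,
        )
        null_rate = df[df.fraction == 0.0].rejection_rate.iloc[0]
        full_rate = df[df.fraction == 1.0].rejection_rate.iloc[0]
        # 20-locus sets give limited power; this is a directional smoke test
        assert null_rate <= 0.25
        assert full_rate >= 0.7
        assert full_rate > null_rate

    def test_delta_increases_with_causal_fraction(self, small_genome):
        rng = np.random.default_rng(8)
        means = []
        for f in (0.0, 0.5, 1.0):
            ds = [
                delta_for_set(
                    small_genome,
                    draw_functional_set(small_genome, "X", 20, f, seed=rng).index_rows,
                    small_genome.tracks["X"],
                )
                for _ in range(10)
            ]
            means.append(np.mean(ds))
        assert means[0] < means[1] < means[2]

    def test_infer_recovers_planted_fraction(self, small_genome):
        est = CausalProportionEstimator(
            small_genome,
            set_size=20,
            increments=np.arange(0.0, 1.01, 0.25),
            n_sets_per_increment=40,
            seed=9,
        )
        # observed delta taken at the mean of the planted-0.5 library sets
        target = est.deltas_[est.fractions_ == 0.5].mean()
        r = est.infer(target, tolerance=0.02)
        assert r["ci_low"] <= 0.5 <= r["ci_high"]

    def test_infer_zero_delta_interval_contains_zero_causal(self, small_genome):
        est = CausalProportionEstimator(
            small_genome,
            set_size=20,
            increments=np.arange(0.0, 1.01, 0.25),
            n_sets_per_increment=40,
            seed=10,
        )
        target = est.deltas_[est.fractions_ == 0.0].mean()
        r = est.infer(target, tolerance=0.02)
        assert r["ci_low"] <= 0.0 + 1e-9

    def test_infer_without_retained_sets_errors(self, small_genome):
        est = CausalProportionEstimator(
            small_genome,
            set_size=20,
            increments=np.array([0.0]),
            n_sets_per_increment=5,
            seed=11,
        )
        with pytest.raises(ValueError, match="tolerance"):
            est.infer(0.99, tolerance=1e-6)


def test_loci_for_rows_matches_locus_contract(small_genome):
    g = small_genome
    fs = draw_functional_set(g, "X", 8, 0.5, seed=12)
    loci = loci_for_rows(g, fs.index_rows, g.tracks["X"])
    proxy_pos = g.proxy_positions()
    for lc, row in zip(loci, fs.index_rows):
        assert len(lc) >= 1
        # index SNP position is among the locus SNPs
        rel = int(g.positions[row]) - lc.window_start
        assert rel in lc.snp_positions
        assert lc.snp_positions.size == len(np.unique(proxy_pos[int(row)]))
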