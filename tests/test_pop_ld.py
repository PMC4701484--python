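"""LD decay, haplotype blocks, PIC, heritability, thresholds."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from radnet import pop_ld, simdata
from radnet.ld_map import HaploidPanel, maf_filter
from radnet.pop_ld import (
    VarianceComponents,
    bonferroni_threshold,
    classify_blocks,
    dprime_confidence_intervals,
    fit_ld_decay,
    gabriel_blocks,
    haplotype_frequencies,
    haplotype_phenotype_summary,
    heritability,
    hill_weir_expected_r2,
    pic,
)


def _panel(columns):
    arr = np.array(columns, dtype=np.float32).T
    return HaploidPanel(
        [f"L{i}" for i in range(arr.shape[0])],
        [f"m{j}" for j in range(arr.shape[1])],
        arr,
    )


def _positions(marker_ids, chrom, bps):
    return pd.DataFrame({"marker_id": marker_ids, "chromosome": chrom, "bp": bps})


class TestDecay:
    def test_curve_monotone_decreasing(self):
        d = np.linspace(1, 5e6, 200)
        y = hill_weir_expected_r2(d, 1e-5, 100)
        assert np.all(np.diff(y) < 0)

    def test_noise_free_recovery(self):
        d, y = simdata.simulate_decay_r2_pairs(1e-5, 100, 300, 2e6, seed=5, noise=False)
        fit = fit_ld_decay(d, y, n_lines=100, background=0.26)
        assert fit.rho == pytest.approx(1e-5, rel=1e-6)
        analytic = pop_ld._decay_crossing(1e-5, 100, 0.26, 2e6)
        assert fit.decay_distance_bp == pytest.approx(analytic, rel=1e-6)

    def test_crossing_by_construction(self):
        # background set to the fitted curve's value at 500 kb -> distance 500 kb
        d, y = simdata.simulate_decay_r2_pairs(2e-6, 189, 300, 3e6, seed=1, noise=False)
        level = float(hill_weir_expected_r2(500_000, 2e-6, 189))
        fit = fit_ld_decay(d, y, n_lines=189, background=level)
        assert fit.decay_distance_bp == pytest.approx(500_000, rel=1e-4)

    def test_background_above_curve_gives_none(self):
        d, y = simdata.simulate_decay_r2_pairs(1e-5, 100, 300, 2e6, seed=5, noise=False)
        fit = fit_ld_decay(d, y, n_lines=100, background=0.99)
        assert fit.decay_distance_bp is None

    def test_decay_distance_monotone_in_background(self):
        d, y = simdata.simulate_decay_r2_pairs(1e-5, 100, 300, 2e6, seed=5, noise=False)
        d1 = fit_ld_decay(d, y, 100, background=0.2).decay_distance_bp
        d2 = fit_ld_decay(d, y, 100, background=0.3).decay_distance_bp
        assert d2 < d1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            fit_ld_decay([1e4] * 10, [0.5] * 10, 100)


class TestDPrimeCI:
    def test_identical_columns_tight_at_one(self):
        rng = np.random.default_rng(0)
        col = (rng.random(100) < 0.5).astype(np.float64)
        X = np.stack([col, col], axis=1)
        lo, hi = dprime_confidence_intervals(X)
        assert lo[0, 1] >= 0.9 and hi[0, 1] == pytest.approx(1.0)

    def test_independent_columns_low_upper(self):
        rng = np.random.default_rng(1)
        X = (rng.random((200, 2)) < 0.5).astype(np.float64)
        lo, hi = dprime_confidence_intervals(X)
        assert hi[0, 1] < 0.9  # strong recombination evidence

    def test_monomorphic_non_informative(self):
        X = np.stack([np.zeros(50), np.ones(50) * 0], axis=1)
        lo, hi = dprime_confidence_intervals(X)
        assert np.isnan(lo[0, 1]) and np.isnan(hi[0, 1])


class TestGabrielBlocks:
    def test_identical_columns_one_block(self):
        rng = np.random.default_rng(0)
        col = (rng.random(100) < 0.5).astype(np.float64)
        p = _panel([col] * 5)
        pos = _positions(p.marker_ids, "A1", [100_000, 130_000, 180_000, 220_000, 250_000])
        blocks = gabriel_blocks(p, pos)
        assert len(blocks) == 1
        assert blocks[0].start_bp == 100_000 and blocks[0].end_bp == 250_000
        assert blocks[0].length_bp == 150_001
        assert blocks[0].snp_ids == p.marker_ids

    def test_independent_markers_no_blocks(self):
        rng = np.random.default_rng(3)
        p = _panel([(rng.random(200) < 0.5).astype(float) for _ in range(8)])
        pos = _positions(p.marker_ids, "A1", (np.arange(8) + 1) * 150_000)
        assert gabriel_blocks(p, pos) == []

    def test_short_block_removed_by_length_filter(self):
        rng = np.random.default_rng(0)
        col = (rng.random(100) < 0.5).astype(np.float64)
        p = _panel([col] * 3)
        pos = _positions(p.marker_ids, "A1", [10_000, 35_000, 60_000])  # 50 kb span
        assert gabriel_blocks(p, pos) == []

    def test_blocks_never_overlap_and_respect_window(self):
        cfg = simdata.SimConfig(n_lines=150, seed=13)
        planted = [dict(chromosome=0, start_marker=10, n_markers=6),
                   dict(chromosome=0, start_marker=40, n_markers=8)]
        out = simdata.simulate_ld_genotypes(
            cfg, n_chromosomes=1, markers_per_chrom=80, spacing_bp=40_000,
            planted_blocks=planted, independent=True,
        )
        panel = maf_filter(out["panel"])
        pos = out["map"][out["map"].marker_id.isin(panel.marker_ids)]
        blocks = gabriel_blocks(panel, pos)
        for a in range(len(blocks)):
            assert blocks[a].length_bp >= 100_000
            assert blocks[a].end_bp - blocks[a].start_bp <= 10_000_000
            for b in range(a + 1, len(blocks)):
                assert not blocks[a].overlaps(blocks[b])

    def test_unsorted_positions_rejected(self):
        p = _panel([[0.0, 1.0, 0.0, 1.0]] * 2)
        pos = _positions(p.marker_ids, "A1", [200_000, 100_000])
        with pytest.raises(ValueError, match="sorted"):
            gabriel_blocks(p, pos)


class TestClassifyBlocks:
    def _mk(self, chrom, start, end, snps):
        return pop_ld.HaplotypeBlock(chrom, start, end, snps)

    def _two_group_panels(self, seed=0, shared_freq=0.5, p2_freq=None):
        rng = np.random.default_rng(seed)
        col1 = (rng.random(60) < shared_freq).astype(float)
        col2 = (rng.random(40) < (p2_freq if p2_freq is not None else shared_freq)).astype(float)
        p1 = HaploidPanel([f"A{i}" for i in range(60)], ["s1", "s2"],
                          np.stack([col1, col1], axis=1))
        p2 = HaploidPanel([f"B{i}" for i in range(40)], ["s1", "s2"],
                          np.stack([col2, col2], axis=1))
        return p1, p2

    def test_specific_block(self):
        p1, p2 = self._two_group_panels()
        b1 = self._mk("A1", 100_000, 220_000, ["s1", "s2"])  # 120 kb
        out = classify_blocks([b1], [], p1, p2)
        assert [b.label for b in out] == ["p1_specific"]

    def test_specific_block_below_50kb_dropped(self):
        p1, p2 = self._two_group_panels()
        b1 = self._mk("A1", 100_000, 140_000, ["s1", "s2"])  # 40 kb
        assert classify_blocks([b1], [], p1, p2) == []

    def test_preferential_on_large_frequency_difference(self):
        p1, p2 = self._two_group_panels(shared_freq=0.9, p2_freq=0.35)
        b1 = self._mk("A1", 100_000, 260_000, ["s1", "s2"])
        b2 = self._mk("A1", 150_000, 300_000, ["s1", "s2"])
        out = classify_blocks([b1], [b2], p1, p2)
        assert {b.label for b in out} == {"preferential"}

    def test_common_below_threshold(self):
        p1, p2 = self._two_group_panels(shared_freq=0.6, p2_freq=0.5)
        b1 = self._mk("A1", 100_000, 260_000, ["s1", "s2"])
        b2 = self._mk("A1", 150_000, 300_000, ["s1", "s2"])
        out = classify_blocks([b1], [b2], p1, p2)
        assert {b.label for b in out} == {"common"}

    def test_label_symmetry(self):
        p1, p2 = self._two_group_panels(shared_freq=0.9, p2_freq=0.35)
        only_p1 = self._mk("A1", 1_000_000, 1_200_000, ["s1"])
        b1 = self._mk("A1", 100_000, 260_000, ["s1", "s2"])
        b2 = self._mk("A1", 150_000, 300_000, ["s1", "s2"])
        fwd = classify_blocks([b1, only_p1], [b2], p1, p2)
        rev = classify_blocks([b2], [b1, only_p1], p2, p1)
        swap = {"p1_specific": "p2_specific", "p2_specific": "p1_specific",
                "common": "common", "preferential": "preferential"}
        assert sorted(swap[b.label] for b in fwd) == sorted(b.label for b in rev)


class TestPIC:
    @pytest.mark.parametrize(
        "p,expected", [(0.5, 0.375), (0.0, 0.0), (1.0, 0.0), (0.1, 0.1638)]
    )
    def test_values(self, p, expected):
        assert pic(p) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_bounded(self, p):
        assert pic(p) == pytest.approx(pic(1.0 - p), abs=1e-12)
        assert 0.0 <= pic(p) <= pic(0.5) + 1e-12

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            pic(1.2)


class TestHaplotypePhenotype:
    def test_group_means(self):
        panel = HaploidPanel(
            ["L1", "L2", "L3", "L4"], ["s1"],
            np.array([[0.0], [0.0], [1.0], [1.0]], np.float32),
        )
        phen = {"L1": 40.0, "L2": 42.0, "L3": 36.0, "L4": 38.0}
        table, test = haplotype_phenotype_summary(panel, ["s1"], phen)
        means = dict(zip(table.haplotype, table["mean"]))
        assert means == {"0": 41.0, "1": 37.0}
        assert test["difference"] == pytest.approx(4.0)

    def test_singleton_haplotype_suppressed(self):
        panel = HaploidPanel(
            ["L1", "L2", "L3"], ["s1"],
            np.array([[0.0], [0.0], [1.0]], np.float32),
        )
        phen = {"L1": 40.0, "L2": 42.0, "L3": 36.0}
        table, _ = haplotype_phenotype_summary(panel, ["s1"], phen, min_lines=2)
        assert list(table.haplotype) == ["0"]

    def test_missing_lines_excluded(self):
        panel = HaploidPanel(
            ["L1", "L2", "L3"], ["s1"],
            np.array([[0.0], [np.nan], [0.0]], np.float32),
        )
        table, _ = haplotype_phenotype_summary(panel, ["s1"], {"L1": 1.0, "L2": 2.0, "L3": 3.0})
        assert table.n_lines.sum() == 2

    def test_planted_effect_recovered(self):
        cfg = simdata.SimConfig(n_lines=150, seed=33)
        out = simdata.simulate_ld_genotypes(
            cfg, n_chromosomes=1, markers_per_chrom=40, spacing_bp=40_000,
            planted_blocks=[dict(chromosome=0, start_marker=10, n_markers=4)],
            independent=True,
            phenotype=dict(sigma2_g=1.0, sigma2_ge=0.5, sigma2_e=0.5,
                           n_env=3, n_rep=3, block_effect=3.0),
        )
        truth = out["truth"].blocks.iloc[0]
        snps = [f"chr1_m{j:04d}" for j in range(10, 14)]
        table, test = haplotype_phenotype_summary(
            out["panel"], snps, out["phenotype_line_means"]
        )
        # carriers of the major haplotype got +3: difference recovers it
        assert test is not None
        assert abs(abs(test["difference"]) - 3.0) < 0.8  # Monte-Carlo error


class TestHeritability:
    def test_hand_arithmetic(self):
        vc = VarianceComponents(4.0, 1.0, 1.0, n_env=3, n_rep=3)
        assert heritability(vc) == pytest.approx(0.9)

    def test_zero_genetic_variance(self):
        assert heritability(VarianceComponents(0.0, 1.0, 1.0, 2, 2)) == 0.0

    def test_no_environmental_noise(self):
        assert heritability(VarianceComponents(5.0, 0.0, 0.0, 1, 1)) == 1.0

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            heritability(VarianceComponents(0.0, 0.0, 0.0, 1, 1))

    def test_invalid_components(self):
        with pytest.raises(ValueError):
            VarianceComponents(-1.0, 0.0, 0.0, 1, 1)
        with pytest.raises(ValueError):
            VarianceComponents(1.0, 0.0, 0.0, 0, 1)


class TestBonferroni:
    @pytest.mark.parametrize("n,expected", [(100, 0.01), (1, 1.0)])
    def test_values(self, n, expected):
        assert bonferroni_threshold(n) == pytest.approx(expected)

    def test_marker_panel_scale(self):
        # 1/10,343 markers rounds to 9.7e-5 at two significant digits
        t = bonferroni_threshold(10_343)
        assert t == pytest.approx(9.668e-5, rel=1e-3)
        assert float(f"{t:.1e}") == 9.7e-5

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


def test_haplotype_frequencies_sum_to_one():
    rng = np.random.default_rng(9)
    arr = rng.choice([0.0, 1.0], size=(30, 3)).astype(np.float32)
    panel = HaploidPanel([f"L{i}" for i in range(30)], ["a", "b", "c"], arr)
    table = haplotype_frequencies(panel, ["a", "b", "c"])
    assert table.frequency.sum() == pytest.approx(1.0)
    assert table["count"].sum() == 30
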