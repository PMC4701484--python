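"""Pairwise r^2, background LD, map assignment, MAF filter and pruning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from radnet import ld_map, simdata
from radnet.io_demux import GenotypeMatrix, HET, HOM1, HOM2, MISSING
from radnet.ld_map import (
    BackgroundLD,
    HaploidPanel,
    assign_unmapped,
    background_ld,
    haploidize,
    ld_prune,
    maf_filter,
    marker_maf,
    r2,
    r2_matrix,
)


def _panel(columns, line_prefix="L"):
    arr = np.array(columns, dtype=np.float32).T
    return HaploidPanel(
        [f"{line_prefix}{i}" for i in range(arr.shape[0])],
        [f"m{j}" for j in range(arr.shape[1])],
        arr,
    )


def brute_force_r2(x, y):
    """Oracle: D^2 / (p(1-p)q(1-q)) from the 2x2 haplotype table."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    a, b = x[ok], y[ok]
    n = len(a)
    p, q = a.mean(), b.mean()
    if p in (0, 1) or q in (0, 1):
        return None
    x11 = np.mean((a == 1) & (b == 1))
    D = x11 - p * q
    return D * D / (p * (1 - p) * q * (1 - q))


class TestHaploidize:
    def test_hom_matrix_no_missing(self):
        g = GenotypeMatrix(["L1", "L2"], ["m1"], np.array([[HOM1], [HOM2]], np.int8))
        panel = haploidize(g)
        assert not np.isnan(panel.alleles).any()
        assert panel.alleles[0, 0] == 0 and panel.alleles[1, 0] == 1

    def test_het_becomes_missing(self):
        g = GenotypeMatrix(["L1"], ["m1"], np.array([[HET]], np.int8))
        assert np.isnan(haploidize(g).alleles[0, 0])

    def test_missing_count_oracle(self):
        rng = np.random.default_rng(0)
        calls = rng.choice(np.array([HOM1, HOM2, HET, MISSING], np.int8), (30, 40))
        g = GenotypeMatrix([f"L{i}" for i in range(30)],
                           [f"m{j}" for j in range(40)], calls)
        panel = haploidize(g)
        expected = ((calls == HET) | (calls == MISSING)).sum()
        assert int(np.isnan(panel.alleles).sum()) == expected


class TestR2:
    def test_identical_columns(self):
        p = _panel([[0, 0, 1, 1], [0, 0, 1, 1]])
        assert r2(p, "m0", "m1").r2 == pytest.approx(1.0)

    def test_textbook_example(self):
        # haplotypes AB:3, Ab:1, aB:1, ab:3 -> D = 0.125, r^2 = 0.25
        a = [1, 1, 1, 1, 0, 0, 0, 0]
        b = [1, 1, 1, 0, 1, 0, 0, 0]
        p = _panel([a, b])
        rec = r2(p, "m0", "m1")
        assert rec.r2 == pytest.approx(0.25)
        assert rec.n_lines == 8

    def test_orthogonal_balanced(self):
        p = _panel([[0, 0, 1, 1], [0, 1, 0, 1]])
        assert r2(p, "m0", "m1").r2 == pytest.approx(0.0)

    def test_monomorphic_undefined(self):
        p = _panel([[0, 0, 0, 0], [0, 1, 0, 1]])
        with pytest.raises(ValueError, match="undefined"):
            r2(p, "m0", "m1")

    @pytest.mark.parametrize("seed", range(6))
    def test_against_table_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        x = rng.choice([0.0, 1.0, np.nan], n, p=[0.45, 0.45, 0.1])
        y = rng.choice([0.0, 1.0, np.nan], n, p=[0.45, 0.45, 0.1])
        expected = brute_force_r2(x, y)
        rr, _ = r2_matrix(x[:, None], y[:, None], min_lines=2)
        if expected is None:
            assert np.isnan(rr[0, 0])
        else:
            assert rr[0, 0] == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_label_swap(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.choice([0.0, 1.0], 20)
        y = rng.choice([0.0, 1.0], 20)
        rr, _ = r2_matrix(np.stack([x, y, 1 - x], axis=1))
        if not np.isnan(rr[0, 1]):
            assert rr[0, 1] == pytest.approx(rr[1, 0])
            assert 0.0 <= rr[0, 1] <= 1.0
            # swapping allele labels at one marker leaves r^2 unchanged
            assert rr[2, 1] == pytest.approx(rr[0, 1], abs=1e-12)


class TestBackgroundLD:
    def _anchors(self, ids, chroms):
        return pd.DataFrame(
            {"marker_id": ids, "chromosome": chroms,
             "cm": np.arange(len(ids), dtype=float), "bp": np.nan, "source": "anchor"}
        )

    def test_nearest_rank_percentile(self):
        vals = np.arange(1, 101) / 100.0
        assert ld_map._nearest_rank_percentile(vals, 99) == pytest.approx(0.99)

    def test_all_zero_r2(self):
        # two chromosomes of mutually orthogonal balanced markers
        cols = [[0, 0, 1, 1, 0, 0, 1, 1, 0, 0, 1, 1],
                [0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1]]
        p = _panel(cols)
        anchors = self._anchors(["m0", "m1"], ["c1", "c2"])
        with pytest.warns(UserWarning, match="unstable"):
            bg = background_ld(p, anchors, min_lines=2)
        assert bg.threshold == pytest.approx(0.0)

    def test_same_chromosome_pairs_excluded(self):
        cols = [[0, 0, 1, 1], [0, 0, 1, 1], [0, 1, 0, 1]]
        p = _panel(cols)
        # m0, m1 identical but on the same chromosome: must not raise threshold
        anchors = self._anchors(["m0", "m1", "m2"], ["c1", "c1", "c2"])
        with pytest.warns(UserWarning):
            bg = background_ld(p, anchors, min_lines=2)
        assert bg.threshold == pytest.approx(0.0)
        assert bg.n_pairs == 2  # m0-m2 and m1-m2 only

    def test_monotone_in_distribution(self):
        lo = ld_map._nearest_rank_percentile(np.linspace(0, 0.2, 200), 99)
        hi = ld_map._nearest_rank_percentile(
            np.concatenate([np.linspace(0, 0.2, 200), [0.9, 0.95]]), 99
        )
        assert hi >= lo

    def test_single_chromosome_rejected(self):
        p = _panel([[0, 1, 0, 1], [1, 0, 1, 0]])
        with pytest.raises(ValueError, match=">= 2 chromosomes"):
            background_ld(p, self._anchors(["m0", "m1"], ["c1", "c1"]))


class TestAssignment:
    def _setup(self):
        rng = np.random.default_rng(4)
        anchor_col = rng.choice([0.0, 1.0], 40)
        noise = rng.choice([0.0, 1.0], 40)
        p = _panel([anchor_col, anchor_col, noise])
        anchors = pd.DataFrame(
            {"marker_id": ["m0"], "chromosome": ["A3"], "cm": [45.2],
             "bp": [np.nan], "source": ["anchor"]}
        )
        return p, anchors

    def test_identical_marker_assigned(self):
        p, anchors = self._setup()
        out = assign_unmapped(p, ["m1"], anchors, BackgroundLD(0.26))
        assert len(out) == 1
        row = out.iloc[0]
        assert row.chromosome == "A3" and row.cm == pytest.approx(45.2)
        assert row.source == "ld_assigned" and row.r2 == pytest.approx(1.0)

    def test_below_background_unassigned(self):
        p, anchors = self._setup()
        out = assign_unmapped(p, ["m2"], anchors, BackgroundLD(0.26))
        assert out.empty

    def test_never_assigns_at_or_below_threshold(self):
        p, anchors = self._setup()
        # threshold 1.0: even a perfect proxy (r^2 = 1) must NOT be assigned
        out = assign_unmapped(p, ["m1", "m2"], anchors, BackgroundLD(1.0))
        assert out.empty

    def test_order_permutation_invariant(self):
        rng = np.random.default_rng(8)
        cols = [rng.choice([0.0, 1.0], 60) for _ in range(6)]
        cols.append(cols[0].copy())  # m6 mirrors anchor m0
        p = _panel(cols)
        anchors = pd.DataFrame(
            {"marker_id": [f"m{j}" for j in range(6)],
             "chromosome": ["A1", "A1", "A2", "A2", "A3", "A3"],
             "cm": np.arange(6, dtype=float), "bp": np.nan, "source": "anchor"}
        )
        a = assign_unmapped(p, ["m6"], anchors, BackgroundLD(0.26))
        b = assign_unmapped(p, ["m6"], anchors.iloc[::-1].reset_index(drop=True),
                            BackgroundLD(0.26))
        assert a.iloc[0].chromosome == b.iloc[0].chromosome
        assert a.iloc[0].cm == b.iloc[0].cm


class TestMafFilter:
    def test_kept_at_030(self):
        col = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        p = _panel([col])
        assert maf_filter(p, 0.05).marker_ids == ["m0"]
        assert marker_maf(p)[0] == pytest.approx(0.3)

    def test_removed_at_004(self):
        col = [1.0] + [0.0] * 24
        p = _panel([col])
        assert marker_maf(p)[0] == pytest.approx(0.04)
        assert maf_filter(p, 0.05).marker_ids == []

    def test_monomorphic_removed(self):
        p = _panel([[0.0] * 10])
        assert maf_filter(p).marker_ids == []


class TestPrune:
    def test_identical_pair_one_retained(self):
        col = np.array([0, 0, 1, 1, 0, 1] * 3, dtype=float)
        p = _panel([col, col.copy()])
        assert len(ld_prune(p)) == 1

    def test_independent_all_retained(self):
        rng = np.random.default_rng(1)
        cols = [rng.choice([0.0, 1.0], 400) for _ in range(8)]
        p = _panel(cols)
        kept = ld_prune(p, r2_threshold=0.4)
        assert kept == p.marker_ids  # random columns at n=400: r^2 ~ 0

    def test_postcondition_audit(self):
        """No retained within-window pair may exceed the threshold."""
        cfg = simdata.SimConfig(n_lines=120, seed=21, ld_rho=1e-6)
        out = simdata.simulate_ld_genotypes(
            cfg, n_chromosomes=1, markers_per_chrom=200, spacing_bp=20_000
        )
        panel = maf_filter(out["panel"])
        kept = ld_prune(panel, window=50, step=5, r2_threshold=0.4)
        sub = panel.subset(kept)
        idx = {m: i for i, m in enumerate(panel.marker_ids)}
        rr, _ = r2_matrix(sub.alleles)
        # audit every pair that shares at least one examined window
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                i, j = idx[kept[a]], idx[kept[b]]
                shares_window = any(
                    s <= i and j < s + 50 for s in range(0, panel.n_markers, 5)
                )
                if shares_window and not np.isnan(rr[a, b]):
                    assert rr[a, b] <= 0.4 + 1e-9
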