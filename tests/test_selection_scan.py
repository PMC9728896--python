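import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popscan.diversity import WindowSpec
from popscan.genotype_io import PopulationMap
from popscan.reference import ref_fst_wc
from popscan.selection_scan import (
    annotate_regions,
    call_sweeps,
    read_gene_intervals,
    site_fst_wc,
    window_scan,
)

from conftest import make_gm


class TestSiteFstWc:
    def test_fixed_difference_is_one(self):
        a, d = site_fst_wc([1.0], [20], [0.0], [20])
        assert a[0] / d[0] == pytest.approx(1.0)

    def test_no_differentiation_nonpositive_numerator(self):
        for p in (0.1, 0.5, 0.9):
            a, _ = site_fst_wc([p], [20], [p], [30])
            assert a[0] <= 0

    def test_small_group_skipped(self):
        a, d = site_fst_wc([0.5], [1], [0.5], [20])
        assert np.isnan(a[0]) and np.isnan(d[0])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_independent_wc84_coding_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(2, 60)), int(rng.integers(2, 60))
        p1, p2 = rng.random(), rng.random()
        a, d = site_fst_wc([p1], [n1], [p2], [n2])
        ra, rd = ref_fst_wc(p1, n1, p2, n2)
        assert a[0] == pytest.approx(ra, abs=1e-10)
        assert d[0] == pytest.approx(rd, abs=1e-10)


def _two_group_pm(n_per):
    m = {f"s{i}": "wild" for i in range(n_per)}
    m.update({f"s{n_per + i}": "dom" for i in range(n_per)})
    return PopulationMap(m)


class TestWindowScan:
    def test_identical_pools_zero_fst_and_rod(self, small_sim):
        gm, pm, _ = small_sim
        same = PopulationMap(
            {
                s: ("a" if i % 2 == 0 else "b")
                for i, s in enumerate(pm.samples_in("wild"))
            }
        )
        # same deme split arbitrarily into two pools: fst ~ 0
        wt = window_scan(gm, same, "a", "b", WindowSpec(30_000, 30_000))
        assert abs(np.nanmean(wt.fst)) < 0.05

    def test_rod_definition(self):
        # construct so pi_dom = pi_wild / 2 exactly -> rod = 0.5
        wt = pd.DataFrame(
            dict(chrom=["c"], start=[1], end=[100], n_sites=[5],
                 fst=[0.5], pi_wild=[0.004], pi_dom=[0.002],
                 rod=[1 - 0.002 / 0.004], pi_ratio=[2.0])
        )
        assert wt.rod[0] == 0.5

    def test_same_pool_both_sides_rod_zero(self):
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, size=(40, 12)).astype(np.int8)
        dos = np.concatenate([dos, dos], axis=1)  # dom columns copy wild
        gm = make_gm(dos, pos=np.arange(1, 41) * 20, chrom_lengths={"chr1": 1_000})
        pm = _two_group_pm(12)
        wt = window_scan(gm, pm, "wild", "dom", WindowSpec(1_000, 1_000))
        assert wt.rod[0] == pytest.approx(0.0)
        assert wt.pi_ratio[0] == pytest.approx(1.0)

    def test_brute_force_window_recomputation(self, small_sim):
        gm, pm, _ = small_sim
        wt = window_scan(gm, pm, "wild", "dom", WindowSpec(20_000, 10_000))
        # recompute one non-empty window by direct per-site summation
        row = wt[wt.n_sites > 3].iloc[0]
        mask = (
            (gm.chrom == row.chrom)
            & (gm.pos >= row.start)
            & (gm.pos <= row.end)
        )
        idx_w = gm.sample_indices(pm.samples_in("wild"))
        idx_d = gm.sample_indices(pm.samples_in("dom"))
        num = den = 0.0
        for i in np.flatnonzero(mask):
            dw, dd = gm.dosages[i, idx_w], gm.dosages[i, idx_d]
            p1, n1 = dw.sum() / (2 * len(dw)), 2 * len(dw)
            p2, n2 = dd.sum() / (2 * len(dd)), 2 * len(dd)
            a, d = ref_fst_wc(float(p1), n1, float(p2), n2)
            num += a
            den += d
        assert row.fst == pytest.approx(num / den, abs=1e-10)

    def test_label_swap_symmetry(self, small_sim):
        gm, pm, _ = small_sim
        wt1 = window_scan(gm, pm, "wild", "dom", WindowSpec(30_000, 30_000))
        wt2 = window_scan(gm, pm, "dom", "wild", WindowSpec(30_000, 30_000))
        np.testing.assert_allclose(wt1.fst, wt2.fst, atol=1e-12)
        ok = ~np.isnan(wt1.rod) & ~np.isnan(wt2.rod) & (wt1.rod != 1)
        np.testing.assert_allclose(
            wt2.rod[ok], 1 - 1 / (1 - wt1.rod[ok]), atol=1e-9
        )


def _toy_windows(fsts, rods, step=10, size=20):
    n = len(fsts)
    starts = 1 + step * np.arange(n)
    return pd.DataFrame(
        dict(
            chrom=["chr1"] * n,
            start=starts,
            end=starts + size - 1,
            n_sites=[5] * n,
            fst=fsts,
            pi_wild=[0.004] * n,
            pi_dom=[0.002] * n,
            rod=rods,
            pi_ratio=[2.0] * n,
        )
    )


class TestCallSweeps:
    def test_toy_merge_of_overlapping_qualifiers(self):
        fst = [0.0, 0.01, 0.02, 0.55, 0.55, 0.03, 0.02, 0.01, 0.0, 0.02]
        rod = [0.0] * 10
        rod[3] = rod[4] = 0.5
        regions, wt = call_sweeps(_toy_windows(fst, rod))
        assert len(regions) == 1
        r = regions.iloc[0]
        # windows 4 and 5 (1-based starts 31 and 41, size 20) merge
        assert (r.start, r.end) == (31, 60)
        assert r.n_windows == 2
        assert r.max_fst == pytest.approx(0.55)
        assert int(wt.qualifies.sum()) == 2

    def test_all_zero_fst_no_regions(self):
        regions, _ = call_sweeps(_toy_windows([0.0] * 12, [0.9] * 12))
        assert len(regions) == 0

    def test_adjacent_windows_merge_but_distant_do_not(self):
        fst = [0.6, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.6]
        rod = [0.5] + [0.0] * 8 + [0.5]
        regions, _ = call_sweeps(_toy_windows(fst, rod, step=30, size=20))
        assert len(regions) == 2

    def test_thresholds_monotone(self):
        rng = np.random.default_rng(0)
        fst = rng.uniform(0, 0.6, 50)
        rod = rng.uniform(0, 0.8, 50)
        prev_bp = None
        for fst_abs in (0.1, 0.2, 0.3, 0.4):
            regions, _ = call_sweeps(_toy_windows(fst, rod), fst_abs=fst_abs)
            bp = (
                (regions.end - regions.start + 1).sum() if len(regions) else 0
            )
            if prev_bp is not None:
                assert bp <= prev_bp
            prev_bp = bp

    def test_all_undefined_warns_empty(self):
        wt = _toy_windows([np.nan] * 12, [0.5] * 12)
        with pytest.warns(UserWarning):
            regions, _ = call_sweeps(wt)
        assert len(regions) == 0


class TestAnnotateRegions:
    def regions(self):
        return pd.DataFrame(
            dict(chrom=["chr1", "chr1"], start=[100, 500], end=[200, 600],
                 n_windows=[1, 1], max_fst=[0.5, 0.5], max_rod=[0.5, 0.5])
        )

    def test_boundary_abutting_gene_not_assigned(self):
        genes = pd.DataFrame(
            dict(chrom=["chr1"], start=[201], end=[250], gene_id=["g1"])
        )
        out = annotate_regions(self.regions(), genes)
        assert out.genes.tolist() == ["", ""]

    def test_gene_spanning_two_regions_in_both(self):
        genes = pd.DataFrame(
            dict(chrom=["chr1"], start=[150], end=[550], gene_id=["g1"])
        )
        out = annotate_regions(self.regions(), genes)
        assert out.genes.tolist() == ["g1", "g1"]

    def test_unknown_chromosome_skipped_with_warning(self):
        genes = pd.DataFrame(
            dict(chrom=["chrZ"], start=[1], end=[10**6], gene_id=["g1"])
        )
        with pytest.warns(UserWarning, match="unknown"):
            out = annotate_regions(self.regions(), genes, known_chroms=["chr1"])
        assert out.n_genes.sum() == 0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_quadratic_overlap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_r, n_g = int(rng.integers(1, 6)), int(rng.integers(1, 12))
        rs = np.sort(rng.integers(1, 500, size=(n_r, 2)), axis=1)
        # separate regions so they are non-overlapping and sorted
        rs = rs[np.argsort(rs[:, 0])]
        regions = pd.DataFrame(
            dict(chrom=["chr1"] * n_r, start=rs[:, 0], end=rs[:, 1] + 1,
                 n_windows=1, max_fst=0.5, max_rod=0.5)
        )
        gs = np.sort(rng.integers(1, 500, size=(n_g, 2)), axis=1)
        genes = pd.DataFrame(
            dict(chrom=["chr1"] * n_g, start=gs[:, 0], end=gs[:, 1],
                 gene_id=[f"g{i}" for i in range(n_g)])
        )
        out = annotate_regions(regions, genes)
        for _, r in out.iterrows():
            expected = sorted(
                g.gene_id
                for _, g in genes.iterrows()
                if g.start <= r.end and g.end >= r.start
            )
            got = sorted(x for x in r.genes.split(",") if x)
            assert got == expected


class TestGeneIntervalIO:
    def test_bed_converts_to_one_based(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t99\t200\tgeneA\nchr2\t0\t50\tgeneB\n")
        df = read_gene_intervals(str(p))
        assert df.start.tolist() == [100, 1]
        assert df.end.tolist() == [200, 50]
        assert df.gene_id.tolist() == ["geneA", "geneB"]

    def test_gff3_gene_features_only(self, tmp_path):
        p = tmp_path / "genes.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t100\t200\t.\t+\t.\tID=gene1;Name=foo\n"
            "chr1\tsrc\tmRNA\t100\t200\t.\t+\t.\tID=t1;Parent=gene1\n"
            "chr1\tsrc\tgene\t300\t400\t.\t-\t.\tName=bar\n"
        )
        df = read_gene_intervals(str(p))
        assert df.gene_id.tolist() == ["gene1", "bar"]
        assert df.start.tolist() == [100, 300]
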