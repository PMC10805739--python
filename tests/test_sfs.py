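import itertools

import numpy as np
import pytest

from conftest import make_matrix
from petreldemog.sfs import (
    MISSING,
    FoldedSFS,
    fold_joint,
    fold_sfs,
    genotypes_to_sfs,
    project_sfs,
    read_dart_csv,
    read_sfs,
    read_vcf,
    suggest_projection,
    write_dart_csv,
    write_sfs,
    write_vcf,
)


class TestFold:
    def test_fold_by_definition_n4(self):
        folded = fold_sfs(np.array([0.0, 10, 4, 2, 0]))
        np.testing.assert_array_equal(folded.data, [0, 12, 4])
        assert folded.mask[0] and not folded.mask[1:].any()

    def test_symmetric_input_doubles_lower_half(self):
        xs = np.array([0.0, 3, 7, 5, 7, 3, 0])  # n=6, symmetric
        folded = fold_sfs(xs)
        np.testing.assert_array_equal(folded.data[1:], [6, 14, 5])

    def test_fold_collects_monomorphic_mass_in_masked_corner(self):
        folded = fold_sfs(np.array([5.0, 1, 1, 1, 9]))
        assert folded.data[0] == 14
        assert folded.total() == 3  # masked corner excluded

    def test_joint_fold_reflects_pooled_majority_and_keeps_ties(self):
        n1 = n2 = 2
        u = np.zeros((3, 3))
        u[2, 2] = 5  # pooled count 4 > 2: reflect to (0,0) corner
        u[2, 1] = 3  # pooled 3 > 2 -> reflect to (0,1)
        u[1, 1] = 2  # pooled 2 == half: tie stays put
        f = fold_joint(u)
        assert f.data[0, 0] == 5 and f.mask[0, 0]
        assert f.data[0, 1] == 3
        assert f.data[1, 1] == 2
        assert f.data[2, 2] == 0


class TestProject:
    def test_identity_when_target_equals_size(self):
        counts = np.array([0.0, 5, 3, 2, 0])
        proj, lost = project_sfs(counts, 4)
        np.testing.assert_array_equal(proj, counts)

    def test_hand_computed_case_n4_to_2(self):
        # all mass in class i=1 of n=4; C(1,1)C(3,1)/C(4,2) = 1/2
        proj, lost = project_sfs(np.array([0.0, 10, 0, 0, 0]), 2)
        assert proj[1] == pytest.approx(5.0)
        assert lost == pytest.approx(5.0)

    def test_projection_mass_conservation(self):
        rng = np.random.default_rng(1)
        counts = np.concatenate([[0.0], rng.integers(0, 50, 9), [0.0]]).astype(float)
        proj, lost = project_sfs(counts, 6)
        # retained + lost-to-monomorphic = input total
        assert proj.sum() == pytest.approx(counts.sum(), abs=1e-9)
        assert proj[1:6].sum() + lost == pytest.approx(counts.sum(), abs=1e-9)
        assert proj[0] + proj[6] == pytest.approx(lost, abs=1e-9)

    def test_matches_monte_carlo_subsampling(self):
        rng = np.random.default_rng(7)
        counts = np.zeros(11)
        counts[1:10] = rng.integers(1, 30, 9)
        proj, _ = project_sfs(counts, 6)
        # resampling oracle: draw 6 of 10 haploids without replacement
        acc = np.zeros(7)
        n_rep = 40000
        alleles = []
        for i, c in enumerate(counts):
            alleles += [i] * int(c)
        draws = rng.random((n_rep, 10)).argsort(axis=1)[:, :6]
        for i, c in enumerate(counts):
            if c == 0:
                continue
            hap = np.zeros(10)
            hap[:i] = 1
            sub = hap[draws].sum(axis=1).astype(int)
            acc += c * np.bincount(sub, minlength=7) / n_rep
        se = 3 * np.sqrt(np.maximum(acc, 1) / n_rep)
        assert (np.abs(proj - acc) < np.maximum(3 * se, 0.2)).all()

    def test_target_above_size_rejected(self):
        with pytest.raises(ValueError):
            project_sfs(np.zeros(5), 10)


class TestGenotypesToSfs:
    def test_single_het_pair_lands_in_class_two(self):
        G = make_matrix([[1], [1]])
        unfolded = genotypes_to_sfs(G, {"p": ["S0", "S1"]}, fold=False)
        assert unfolded.data[2] == pytest.approx(1.0)
        folded = genotypes_to_sfs(G, {"p": ["S0", "S1"]}, fold=True)
        assert folded.data[2] == pytest.approx(1.0)

    def test_monomorphic_matrix_has_no_polymorphic_mass(self):
        G = make_matrix(np.zeros((3, 4), dtype=int))
        s = genotypes_to_sfs(G, {"p": ["S0", "S1", "S2"]}, fold=True)
        assert s.total() == pytest.approx(0.0)

    def test_missing_projection_matches_enumeration_oracle(self):
        # genotypes (0, 1, missing): 4 called haploids (0,0,0,1), project to 4
        G = make_matrix([[0], [1], [MISSING]])
        s = genotypes_to_sfs(
            G, {"p": ["S0", "S1", "S2"]}, fold=False, projection={"p": 4}
        )
        # brute force over all 4-haploid subsamples of the 4 observed: identity
        assert s.data[1] == pytest.approx(1.0)
        # project to 2: average over all C(4,2) pairs of haploids
        s2 = genotypes_to_sfs(
            G, {"p": ["S0", "S1", "S2"]}, fold=False, projection={"p": 2}
        )
        haps = [0, 0, 0, 1]
        acc = np.zeros(3)
        combos = list(itertools.combinations(range(4), 2))
        for c in combos:
            acc[sum(haps[i] for i in c)] += 1 / len(combos)
        np.testing.assert_allclose(s2.data, acc, atol=1e-12)

    def test_snp_with_insufficient_haploids_contributes_nothing(self):
        G = make_matrix([[1], [MISSING], [MISSING]])
        s = genotypes_to_sfs(G, {"p": ["S0", "S1", "S2"]}, fold=False, projection={"p": 4})
        assert s.data.sum() == pytest.approx(0.0)

    def test_invariant_to_sample_and_locus_order(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(6, 40))
        G = make_matrix(calls)
        ids = G.sample_ids
        s1 = genotypes_to_sfs(G, {"p": ids}, fold=True)
        perm = rng.permutation(6)
        lperm = rng.permutation(40)
        G2 = make_matrix(calls[perm][:, lperm])
        s2 = genotypes_to_sfs(G2, {"p": G2.sample_ids}, fold=True)
        np.testing.assert_allclose(s1.data, s2.data, atol=1e-9)

    def test_2d_marginals_equal_1d_spectra(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 3, size=(8, 60))
        G = make_matrix(calls)
        ids = G.sample_ids
        pops = {"a": ids[:4], "b": ids[4:]}
        joint = genotypes_to_sfs(G, pops, fold=False)
        m_a = genotypes_to_sfs(G, {"a": pops["a"]}, fold=False)
        np.testing.assert_allclose(joint.data.sum(axis=1), m_a.data, atol=1e-9)

    def test_projection_target_below_two_rejected(self):
        G = make_matrix([[1], [1]])
        with pytest.raises(ValueError):
            genotypes_to_sfs(G, {"p": ["S0", "S1"]}, projection={"p": 1})

    def test_no_missing_folded_total_equals_segregating_sites(self):
        rng = np.random.default_rng(11)
        calls = rng.integers(0, 3, size=(5, 80))
        G = make_matrix(calls)
        seg = (~G.is_monomorphic()).sum()
        s = genotypes_to_sfs(G, {"p": G.sample_ids}, fold=True)
        assert s.total() == pytest.approx(seg)


class TestSuggestProjection:
    def test_complete_data_recommends_full_size(self):
        rng = np.random.default_rng(2)
        G = make_matrix(rng.integers(0, 3, size=(5, 50)))
        table, best = suggest_projection(G, G.sample_ids)
        assert best == 10

    def test_entirely_missing_sample_recommends_one_fewer_diploid(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 3, size=(5, 50))
        calls[0] = MISSING
        G = make_matrix(calls)
        _, best = suggest_projection(G, G.sample_ids)
        assert best == 8

    def test_half_missing_sample_lowers_recommendation_exhaustively(self):
        # exhaustive-scan oracle on a 5x20 matrix where one bird is 50% missing
        rng = np.random.default_rng(9)
        calls = rng.integers(0, 3, size=(5, 20))
        calls[0, ::2] = MISSING
        G = make_matrix(calls)
        table, best = suggest_projection(G, G.sample_ids)
        assert best < 10
        # oracle: recompute expectation by direct hypergeometric sums
        from scipy.stats import hypergeom

        obs = G.calls != MISSING
        alt = np.where(obs, G.calls, 0).sum(axis=0)
        nn = 2 * obs.sum(axis=0)
        for _, row in table.iterrows():
            m = int(row["target"])
            expect = sum(
                1 - hypergeom.pmf(0, n_l, a_l, m) - hypergeom.pmf(m, n_l, a_l, m)
                for a_l, n_l in zip(alt, nn)
                if n_l >= m
            )
            assert row["expected_segregating"] == pytest.approx(expect, abs=1e-9)


class TestIO:
    def test_vcf_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        calls = rng.integers(-1, 3, size=(4, 30))
        G = make_matrix(calls)
        p = tmp_path / "x.vcf"
        write_vcf(G, p)
        back = read_vcf(p)
        np.testing.assert_array_equal(back.calls, G.calls)
        assert back.sample_ids == G.sample_ids

    def test_vcf_missing_cell_count(self, tmp_path):
        G = make_matrix([[0, 1], [2, MISSING], [1, 0]])
        p = tmp_path / "y.vcf"
        write_vcf(G, p)
        back = read_vcf(p)
        assert (back.calls == MISSING).sum() == 1

    def test_triallelic_sites_dropped(self, tmp_path):
        p = tmp_path / "tri.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=c>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS0\tS1\n"
            "c\t1\tl1\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0\n"
            "c\t2\tl2\tA\tT,G\t.\tPASS\t.\tGT\t0/1\t0/2\n"
        )
        back = read_vcf(p)
        assert back.n_loci == 1

    def test_dart_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        calls = rng.integers(-1, 3, size=(3, 10))
        G = make_matrix(
            calls,
            locus_meta={
                "tag_id": [f"T{j}" for j in range(10)],
                "chrom": ["c"] * 10,
                "pos": list(range(1, 11)),
                "call_rate": np.linspace(0.8, 1, 10),
                "rep_avg": [0.99] * 10,
                "avg_read_depth": [20.0] * 10,
            },
        )
        p = tmp_path / "d.csv"
        write_dart_csv(G, p)
        back = read_dart_csv(p)
        np.testing.assert_array_equal(back.calls, G.calls)

    @pytest.mark.parametrize("dialect", ["fastsimcoal-obs", "dadi"])
    def test_sfs_round_trip_1d(self, tmp_path, dialect):
        s = FoldedSFS(np.array([0.0, 12, 4, 2]), (6,), np.array([True, False, False, False]))
        p = tmp_path / "s.obs"
        write_sfs(s, p, dialect)
        back = read_sfs(p, dialect)
        np.testing.assert_allclose(back.data, s.data)

    @pytest.mark.parametrize("dialect", ["fastsimcoal-obs", "dadi"])
    def test_sfs_round_trip_2d(self, tmp_path, dialect):
        u = np.arange(12, dtype=float).reshape(3, 4)
        s = fold_joint(u, pop_names=("RIR", "RDC"))
        p = tmp_path / "s2.obs"
        write_sfs(s, p, dialect)
        back = read_sfs(p, dialect)
        np.testing.assert_allclose(back.data, s.data)

    def test_fsc_header_format(self, tmp_path):
        s = fold_sfs(np.array([0.0, 5, 3, 2, 1, 0, 0]))
        p = tmp_path / "h.obs"
        write_sfs(s, p, "fastsimcoal-obs")
        lines = p.read_text().splitlines()
        assert lines[0] == "1 observations"
        assert lines[1].startswith("d0_0 d0_1")
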