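import itertools

import numpy as np
import pytest
from scipy.stats import pearsonr

from gutmaz.community_metrics import (
    DistanceMatrix,
    alpha_diversity,
    bray_curtis,
    bray_curtis_pcoa,
    filter_rare_otus,
    mantel_test,
    pairwise_wilcoxon_holm,
    pcoa,
    permanova,
    qc_filter_reads,
    rarefy_averaged,
)
from gutmaz.io_core import OtuTable


def _fastq_record(name, seq, quals):
    qstr = "".join(chr(q + 33) for q in quals)
    return f"@{name}\n{seq}\n+\n{qstr}\n"


class TestQcFilterReads:
    def test_length_rule(self, tmp_path):
        p = tmp_path / "in.fastq"
        p.write_text(_fastq_record("r1", "A" * 74 + "C" * 75, [30] * 149))
        tallies = qc_filter_reads(p)
        assert tallies["too_short"] == 1 and tallies["kept"] == 0

    def test_quality_rule(self, tmp_path):
        p = tmp_path / "in.fastq"
        seq = "AC" * 100
        p.write_text(_fastq_record("r1", seq, [19] * 200))
        tallies = qc_filter_reads(p)
        assert tallies["low_quality"] == 1 and tallies["kept"] == 0

    def test_boundaries_kept(self, tmp_path):
        # exactly 150 bp at exactly Q20 with 8-bp homopolymer passes
        p = tmp_path / "in.fastq"
        seq = ("A" * 8 + "C" * 8) * 9 + "ACGTAC"
        assert len(seq) == 150
        p.write_text(_fastq_record("r1", seq, [20] * 150))
        tallies = qc_filter_reads(p)
        assert tallies["kept"] == 1

    def test_ambiguous_and_homopolymer(self, tmp_path):
        p = tmp_path / "in.fastq"
        recs = _fastq_record("r1", "ACGT" * 40 + "N" + "ACG", [30] * 164)
        recs += _fastq_record("r2", "A" * 9 + "CGTA" * 40, [30] * 169)
        p.write_text(recs)
        tallies = qc_filter_reads(p)
        assert tallies["ambiguous"] == 1
        assert tallies["homopolymer"] == 1
        assert tallies["kept"] == 0

    def test_planted_batch_matches_enumeration_oracle(self, tmp_path, rng):
        # 1000 random reads; oracle = independent per-read rule check
        reads = []
        for i in range(1000):
            length = int(rng.integers(140, 210))
            bases = rng.choice(list("ACGT"), size=length)
            if rng.random() < 0.1:
                bases[rng.integers(0, length)] = "N"
            if rng.random() < 0.1:
                start = int(rng.integers(0, length - 10))
                bases[start : start + 10] = "G"
            q = rng.integers(15, 40, size=length)
            reads.append(("r%d" % i, "".join(bases), q.tolist()))
        p = tmp_path / "in.fastq"
        p.write_text("".join(_fastq_record(*r) for r in reads))
        out = tmp_path / "out.fastq"
        tallies = qc_filter_reads(p, out)

        def oracle_keep(seq, q):
            if len(seq) < 150 or np.mean(q) < 20:
                return False
            if set(seq) - set("ACGT"):
                return False
            runs = max(len(list(g)) for _, g in itertools.groupby(seq))
            return runs <= 8

        expected_kept = sum(oracle_keep(s, q) for _, s, q in reads)
        assert tallies["kept"] == expected_kept
        assert tallies["kept"] + tallies["discarded"] == 1000
        assert out.read_text().count("\n") == 4 * expected_kept


class TestFilterRareOtus:
    def test_threshold_arithmetic(self):
        # grand total 1,000,000: OTU with 9 reads dropped, 10 kept
        counts = np.zeros((1, 3), dtype=int)
        counts[0] = [999_981, 9, 10]
        t = OtuTable(["s"], ["big", "nine", "ten"], counts)
        out = filter_rare_otus(t)
        assert out.otu_ids == ["big", "ten"]

    def test_identity_when_all_abundant(self, small_table):
        assert filter_rare_otus(small_table) == small_table

    def test_matches_brute_force_scan(self, random_table):
        out = filter_rare_otus(random_table)
        grand = random_table.counts.sum()
        survivors = [
            o
            for j, o in enumerate(random_table.otu_ids)
            if random_table.counts[:, j].sum() >= 1e-5 * grand
        ]
        assert out.otu_ids == survivors


class TestRarefyAveraged:
    def test_single_otu_forced_outcome(self):
        t = OtuTable(["s"], ["o"], np.array([[1000]]))
        rt = rarefy_averaged(t, n_resamples=5, depth_fraction=0.9, seed=0)
        assert rt.target_depth == 900
        assert rt.values[0, 0] == 900

    def test_hypergeometric_expectation_oracle(self):
        t = OtuTable(["s"], ["a", "b"], np.array([[600, 400]]))
        rt = rarefy_averaged(t, n_resamples=100, depth_fraction=0.9, seed=1)
        # sampling 900 of 1000 without replacement: E = (540, 360),
        # per-draw var = d*p*(1-p)*(N-d)/(N-1)
        var = 900 * 0.6 * 0.4 * (1000 - 900) / 999
        se = np.sqrt(var / 100)
        assert abs(rt.raw_mean[0, 0] - 540) < 3 * se
        assert abs(rt.raw_mean[0, 1] - 360) < 3 * se

    def test_pre_rounding_depth_exact(self, random_table):
        rt = rarefy_averaged(random_table, n_resamples=20, seed=2)
        assert np.allclose(rt.raw_mean.sum(axis=1), rt.target_depth, atol=1e-9)

    def test_rounded_sums_near_target(self, random_table):
        rt = rarefy_averaged(random_table, n_resamples=20, seed=2)
        slack = random_table.n_otus / 2
        assert np.all(np.abs(rt.values.sum(axis=1) - rt.target_depth) <= slack)

    def test_deterministic(self, random_table):
        a = rarefy_averaged(random_table, n_resamples=10, seed=7)
        b = rarefy_averaged(random_table, n_resamples=10, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_zero_depth_rejected(self):
        t = OtuTable(["s1", "s2"], ["o"], np.array([[5], [0]]))
        with pytest.raises(ValueError, match="s2"):
            rarefy_averaged(t)


class TestAlphaDiversity:
    def test_uniform_four_otus_shannon_two_bits(self):
        t = OtuTable(["s"], list("abcd"), np.array([[25, 25, 25, 25]]))
        a = alpha_diversity(t)
        assert a.loc["s", "shannon"] == pytest.approx(2.0)

    def test_single_otu_zero_diversity(self):
        t = OtuTable(["s"], ["a"], np.array([[100]]))
        a = alpha_diversity(t)
        assert a.loc["s", "shannon"] == 0.0
        assert a.loc["s", "simpson"] == 0.0

    def test_chao1_formula(self):
        # S_obs=5, F1=2, F2=1 -> 5 + 4/2 = 7
        t = OtuTable(["s"], list("abcde"), np.array([[1, 1, 2, 5, 5]]))
        a = alpha_diversity(t)
        assert a.loc["s", "chao1"] == pytest.approx(7.0)

    def test_chao1_f2_zero_correction(self):
        t = OtuTable(["s"], list("abc"), np.array([[1, 1, 5]]))
        a = alpha_diversity(t)
        assert a.loc["s", "chao1"] == pytest.approx(3 + 2 * 1 / 2)

    def test_natural_log_option(self):
        t = OtuTable(["s"], list("abcd"), np.array([[25, 25, 25, 25]]))
        a = alpha_diversity(t, shannon_base=np.e)
        assert a.loc["s", "shannon"] == pytest.approx(np.log(4))

    def test_invariant_to_column_order(self, random_table, rng):
        perm = rng.permutation(random_table.n_otus)
        shuffled = random_table.select_otus(
            [random_table.otu_ids[j] for j in perm]
        )
        a = alpha_diversity(random_table)
        b = alpha_diversity(shuffled)
        assert np.allclose(a.to_numpy(), b.to_numpy())


class TestBrayCurtisPcoa:
    def test_identical_samples_zero_distance(self):
        t = OtuTable(["s1", "s2", "s3"], ["a", "b"], np.array([[3, 7]] * 3))
        d, _, _ = bray_curtis_pcoa(t)
        assert np.allclose(d.matrix, 0.0)

    def test_disjoint_supports_distance_one(self):
        t = OtuTable(
            ["s1", "s2", "s3"],
            list("abcd"),
            np.array([[5, 5, 0, 0], [0, 0, 5, 5], [5, 0, 5, 0]]),
        )
        d, _, _ = bray_curtis_pcoa(t)
        assert d.matrix[0, 1] == pytest.approx(1.0)

    def test_entries_in_unit_interval(self, random_table):
        d = bray_curtis(random_table)
        assert d.matrix.min() >= 0 and d.matrix.max() <= 1

    def test_gram_reconstruction_oracle(self, rng):
        # euclidean distances embed exactly: coords must reproduce the
        # double-centered Gram matrix
        pts = rng.normal(size=(10, 4))
        from scipy.spatial.distance import pdist, squareform

        dmat = squareform(pdist(pts))
        dist = DistanceMatrix([f"s{i}" for i in range(10)], dmat)
        coords, evals = pcoa(dist)
        n = 10
        a = -0.5 * dmat**2
        j = np.eye(n) - np.ones((n, n)) / n
        gram_oracle = j @ a @ j
        assert np.abs(coords @ coords.T - gram_oracle).max() < 1e-8

    def test_axes_ordered_by_eigenvalue(self, random_table):
        _, _, evals = bray_curtis_pcoa(random_table)
        assert np.all(np.diff(evals) <= 1e-12)


class TestPermanova:
    @staticmethod
    def _oracle_exhaustive_p(dmat, labels):
        """Independent brute-force enumeration with from-scratch F."""

        def f_stat(lbls):
            lbls = np.asarray(lbls)
            n = len(lbls)
            groups = sorted(set(lbls.tolist()))
            ss_t = sum(
                dmat[i, j] ** 2 for i in range(n) for j in range(i + 1, n)
            ) / n
            ss_w = 0.0
            for g in groups:
                idx = [i for i in range(n) if lbls[i] == g]
                ss_w += sum(
                    dmat[i, j] ** 2
                    for i in idx
                    for j in idx
                    if i < j
                ) / len(idx)
            ss_a = ss_t - ss_w
            k = len(groups)
            return (ss_a / (k - 1)) / (ss_w / (n - k))

        f_obs = f_stat(labels)
        n_ge = 0
        n_tot = 0
        for perm in itertools.permutations(labels):
            n_tot += 1
            if f_stat(perm) >= f_obs - 1e-12:
                n_ge += 1
        return n_ge / n_tot

    def test_exhaustive_matches_enumeration_oracle(self, rng):
        pts = rng.normal(size=(6, 3))
        pts[3:] += 1.0
        from scipy.spatial.distance import pdist, squareform

        dmat = squareform(pdist(pts))
        dist = DistanceMatrix([f"s{i}" for i in range(6)], dmat)
        labels = ["a", "a", "a", "b", "b", "b"]
        res = permanova(dist, labels, n_perm="all")
        assert res.p_value == pytest.approx(self._oracle_exhaustive_p(dmat, labels))

    def test_two_far_clusters_minimum_p(self, rng):
        pts = rng.normal(size=(12, 2), scale=0.01)
        pts[6:] += 100.0
        from scipy.spatial.distance import pdist, squareform

        dist = DistanceMatrix(
            [f"s{i}" for i in range(12)], squareform(pdist(pts))
        )
        labels = ["a"] * 6 + ["b"] * 6
        res = permanova(dist, labels, n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_r2_in_unit_interval_and_invariance(self, rng):
        pts = rng.normal(size=(12, 3))
        from scipy.spatial.distance import pdist, squareform

        dmat = squareform(pdist(pts))
        labels = np.array(["a"] * 6 + ["b"] * 6)
        ids = [f"s{i}" for i in range(12)]
        r2 = permanova(DistanceMatrix(ids, dmat), labels, n_perm=9).r_squared
        assert 0 <= r2 <= 1
        perm = rng.permutation(12)
        dmat_p = dmat[np.ix_(perm, perm)]
        r2_p = permanova(
            DistanceMatrix(ids, dmat_p), labels[perm], n_perm=9
        ).r_squared
        assert r2_p == pytest.approx(r2)

    def test_singleton_group_rejected(self, rng):
        from scipy.spatial.distance import pdist, squareform

        dmat = squareform(pdist(rng.normal(size=(5, 2))))
        dist = DistanceMatrix([f"s{i}" for i in range(5)], dmat)
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(dist, ["a", "a", "a", "a", "b"])

    def test_type_one_error_calibrated(self, rng):
        # 500 null simulations, n=20, 99 permutations: rejection rate 5% +/- 2%
        from scipy.spatial.distance import pdist, squareform

        labels = ["a"] * 10 + ["b"] * 10
        rejections = 0
        n_sims = 500
        for s in range(n_sims):
            pts = rng.normal(size=(20, 3))
            dist = DistanceMatrix(
                [f"s{i}" for i in range(20)], squareform(pdist(pts))
            )
            if permanova(dist, labels, n_perm=99, seed=s).p_value <= 0.05:
                rejections += 1
        assert abs(rejections / n_sims - 0.05) < 0.02


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        from scipy.spatial.distance import pdist, squareform

        dmat = squareform(pdist(rng.normal(size=(8, 3))))
        dist = DistanceMatrix([f"s{i}" for i in range(8)], dmat)
        r, _ = mantel_test(dist, dist, n_perm=9)
        assert r == pytest.approx(1.0)

    def test_size_mismatch_fails(self, rng):
        from scipy.spatial.distance import pdist, squareform

        d1 = DistanceMatrix(
            ["a", "b", "c"], squareform(pdist(rng.normal(size=(3, 2))))
        )
        d2 = DistanceMatrix(
            ["a", "b", "c", "d"], squareform(pdist(rng.normal(size=(4, 2))))
        )
        with pytest.raises(ValueError, match="different sizes"):
            mantel_test(d1, d2)

    def test_exhaustive_matches_enumeration_oracle(self, rng):
        from scipy.spatial.distance import pdist, squareform

        m1 = squareform(pdist(rng.normal(size=(5, 2))))
        m2 = squareform(pdist(rng.normal(size=(5, 2))))
        ids = [f"s{i}" for i in range(5)]
        r, p = mantel_test(
            DistanceMatrix(ids, m1), DistanceMatrix(ids, m2), n_perm="all"
        )
        iu = np.triu_indices(5, 1)
        x = m1[iu]
        r_obs = pearsonr(x, m2[iu]).statistic
        n_ge = 0
        n_tot = 0
        for perm in itertools.permutations(range(5)):
            n_tot += 1
            y = m2[np.ix_(perm, perm)][iu]
            if abs(pearsonr(x, y).statistic) >= abs(r_obs) - 1e-12:
                n_ge += 1
        assert r == pytest.approx(r_obs)
        assert p == pytest.approx(n_ge / n_tot)

    def test_null_p_roughly_uniform(self, rng):
        from scipy.spatial.distance import pdist, squareform

        ids = [f"s{i}" for i in range(12)]
        ps = []
        for s in range(100):
            m1 = squareform(pdist(rng.normal(size=(12, 3))))
            m2 = squareform(pdist(rng.normal(size=(12, 3))))
            _, p = mantel_test(
                DistanceMatrix(ids, m1), DistanceMatrix(ids, m2),
                n_perm=99, seed=s,
            )
            ps.append(p)
        # under the null roughly 5% of p-values fall at or below 0.05
        assert 0.0 <= np.mean(np.array(ps) <= 0.05) <= 0.15


class TestPairwiseWilcoxon:
    def test_holm_adjustment_monotone(self, rng):
        vals = np.concatenate(
            [rng.normal(0, 1, 20), rng.normal(2, 1, 20), rng.normal(4, 1, 20)]
        )
        groups = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        df = pairwise_wilcoxon_holm(vals, groups)
        assert len(df) == 3
        assert (df["p_holm"] >= df["p"] - 1e-15).all()

    def test_paired_requires_equal_sizes(self, rng):
        vals = rng.normal(size=30)
        groups = ["a"] * 20 + ["b"] * 10
        with pytest.raises(ValueError, match="equal sizes"):
            pairwise_wilcoxon_holm(vals, groups, paired=True)
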