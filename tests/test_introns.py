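import itertools

import numpy as np
import pandas as pd
import pytest

from clipsplice.annotation import IntronInterval, derive_introns
from clipsplice.introns import (
    ConstantScorer,
    PwmSpliceScorer,
    classify_intron,
    classify_table,
    compare_intron_groups,
    count_intron_reads,
    intron_features,
    size_factors,
    splice_site_contexts,
    train_scorer_from_introns,
)


def reads_df(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    df["name"] = "r"
    df["score"] = 1
    return df


def iv(iid, start, end, chrom="c", strand="+"):
    return IntronInterval(iid, chrom, strand, start, end, gene_id="g")


class TestCountIntronReads:
    def test_overlap_5_counts(self):
        counts = count_intron_reads(reads_df([("c", 95, 105, "+")]), [iv("i1", 100, 200)])
        assert counts["i1"] == 1

    def test_overlap_4_does_not(self):
        counts = count_intron_reads(reads_df([("c", 96, 106, "+")]), [iv("i1", 102, 200)])
        assert counts["i1"] == 0

    def test_strand_mismatch_not_counted(self):
        counts = count_intron_reads(reads_df([("c", 100, 110, "-")]), [iv("i1", 100, 200)])
        assert counts["i1"] == 0

    def test_read_counts_once_to_largest_overlap(self):
        ivs = [iv("i1", 100, 106), iv("i2", 106, 200)]
        counts = count_intron_reads(reads_df([("c", 101, 111, "+")]), ivs)
        assert counts == {"i1": 1, "i2": 0}  # 5 vs 5 overlap: leftmost wins

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        bounds = np.sort(rng.choice(np.arange(0, 5000, 7), 40, replace=False))
        ivs = [iv(f"i{j}", int(a), int(b)) for j, (a, b) in enumerate(zip(bounds[::2], bounds[1::2]))]
        rows = [("c", int(s), int(s) + 10, "+") for s in rng.integers(0, 5000, 1000)]
        got = count_intron_reads(reads_df(rows), ivs, min_overlap=5)
        expect = {x.intron_id: 0 for x in ivs}
        for _, s, e, _ in rows:
            best, best_ov = None, 0
            for x in ivs:
                ov = min(e, x.end) - max(s, x.start)
                if ov > best_ov:
                    best, best_ov = x, ov
            if best is not None and best_ov >= 5:
                expect[best.intron_id] += 1
        assert got == expect


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        m = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        fs, _ = size_factors(m)
        assert fs.tolist() == pytest.approx([1.0, 1.0])

    def test_doubled_sample_factor_ratio_2(self):
        m = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]})
        fs, norm = size_factors(m)
        assert fs["b"] / fs["a"] == pytest.approx(2.0)
        pd.testing.assert_series_equal(norm["a"], norm["b"], check_names=False)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.poisson(100, (50, 4)), columns=list("abcd"))
        fs, _ = size_factors(m)
        mat = m.to_numpy(float)
        keep = (mat > 0).all(axis=1)
        geo = np.exp(np.log(mat[keep]).mean(axis=1))
        expect = [np.median(mat[keep, j] / geo) for j in range(4)]
        assert fs.tolist() == pytest.approx(expect)

    def test_all_zero_gene_hard_error(self):
        with pytest.raises(ValueError):
            size_factors(pd.DataFrame({"a": [0, 0], "b": [1, 0]}))


class TestClassifyIntron:
    def test_clip_plus_all_three_rules(self):
        # 10/2 = 5x; 9/1 >= 5x; control 0 with >= 5 reads
        st = classify_intron([10, 9, 8], [2, 1, 0])
        assert st.status == "CLIP_plus" and st.support == 3

    def test_clip_minus_all_below_control(self):
        st = classify_intron([1, 0, 2], [1, 1, 2])
        assert st.status == "CLIP_minus"

    def test_single_support_is_neither(self):
        st = classify_intron([10, 1, 1], [1, 1, 1])
        assert st.status == "neither" and st.support == 1

    def test_disjoint_and_monotone_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(10_000):
            c = rng.integers(0, 12, 3)
            k = rng.integers(0, 6, 3)
            st = classify_intron(c, k)
            # CLIP+ and CLIP- disjoint
            if st.status == "CLIP_plus":
                assert not all(ci <= ki for ci, ki in zip(c, k))
            # monotone: bumping any count never demotes CLIP+
            if st.status == "CLIP_plus":
                j = rng.integers(3)
                c2 = c.copy()
                c2[j] += 1
                assert classify_intron(c2, k).status == "CLIP_plus"
            if st.status == "CLIP_minus":
                j = rng.integers(3)
                k2 = k.copy()
                k2[j] += 1
                assert classify_intron(c, k2).status == "CLIP_minus"

    def test_universe_partition(self):
        rng = np.random.default_rng(3)
        tab = pd.DataFrame(
            dict(
                intron_id=[f"i{j}" for j in range(200)],
                gene_id=[f"g{j % 20}" for j in range(200)],
                count_1=rng.integers(0, 10, 200),
                count_2=rng.integers(0, 10, 200),
                count_3=rng.integers(0, 10, 200),
                control_1=rng.integers(0, 4, 200),
            )
        )
        expr = {f"g{j}": (5.0 if j % 4 else 0.1) for j in range(20)}
        out = classify_table(tab, expr, expr_min=1.0)
        n_expressed = sum(expr[g] >= 1.0 for g in tab["gene_id"])
        assert len(out) == n_expressed
        assert set(out["status"]) <= {"CLIP_plus", "CLIP_minus", "neither"}

    def test_missing_control_column_errors(self):
        tab = pd.DataFrame(dict(intron_id=["i"], gene_id=["g"], count_1=[5]))
        with pytest.raises(ValueError):
            classify_table(tab, {"g": 5.0})


class TestIntronFeatures:
    def test_gc_half(self, small_sim, small_fasta):
        ivx = next(iter(small_sim.introns.values()))
        feats = intron_features(ivx, small_fasta, ConstantScorer())
        from clipsplice.seq import fetch, gc_fraction

        body = fetch(small_fasta, ivx.chrom, ivx.start, ivx.end, ivx.strand)
        assert feats.gc == pytest.approx(gc_fraction(body))
        assert feats.length == ivx.length

    def test_constant_scorer_contract(self, small_sim, small_fasta):
        ivx = next(iter(small_sim.introns.values()))
        feats = intron_features(ivx, small_fasta, ConstantScorer(0.0))
        assert feats.ss5_score == 0.0 and feats.ss3_score == 0.0

    def test_consensus_scores_above_scrambled(self):
        donors = ["CAGGTAAGT"] * 50
        acceptors = ["T" * 10 + "C" * 8 + "AG" + "GTA"] * 50
        sc = PwmSpliceScorer.train(donors, acceptors)
        assert sc.score_donor("CAGGTAAGT") > sc.score_donor("GTACAAGGT")
        assert sc.score_acceptor(acceptors[0]) > sc.score_acceptor("ACGT" * 5 + "AGG")

    def test_trained_scorer_separates_classes(self, small_sim, small_fasta):
        introns = list(small_sim.introns.values())
        scorer = train_scorer_from_introns(introns, small_fasta)
        by_class = {"optimal": [], "suboptimal": []}
        for ivx in introns:
            d, _ = splice_site_contexts(ivx, small_fasta)
            by_class[small_sim.intron_class[ivx.intron_id]].append(scorer.score_donor(d))
        assert np.mean(by_class["optimal"]) > np.mean(by_class["suboptimal"])

    def test_contexts_are_canonical(self, small_sim, small_fasta):
        for ivx in list(small_sim.introns.values())[:10]:
            d, a = splice_site_contexts(ivx, small_fasta)
            assert d[3:5] == "GT"
            assert a[18:20] == "AG"


class TestCompareGroups:
    def make_feats(self, values):
        return pd.DataFrame(
            {"length": values, "gc": values, "ss5_score": values, "ss3_score": values},
            index=[f"i{j}" for j in range(len(values))],
        )

    def test_identical_groups_p_near_one(self):
        feats = self.make_feats([1, 2, 3, 1, 2, 3])
        out = compare_intron_groups(feats, ["i0", "i1", "i2"], ["i3", "i4", "i5"])
        assert (out["p_value"] > 0.9).all()
        assert (out["median_clip_plus"] == out["median_clip_minus"]).all()

    def test_exact_rank_sum_enumeration(self):
        feats = self.make_feats([1, 2, 3, 10, 20, 30])
        out = compare_intron_groups(feats, ["i0", "i1", "i2"], ["i3", "i4", "i5"])
        # all 3 below: most extreme of C(6,3)=20 arrangements, two-sided
        assert out["p_value"].iloc[0] == pytest.approx(2 / 20)

    def test_empty_group_errors(self):
        feats = self.make_feats([1, 2])
        with pytest.raises(ValueError):
            compare_intron_groups(feats, ["i0"], ["missing"])

    def test_planted_suboptimal_binding_recovered(self, small_fasta):
        from clipsplice.simulate import GenomeConfig, make_genome

        sim = make_genome(GenomeConfig(n_genes=150), seed=21)
        import pyfaidx, tempfile, os
        from clipsplice.simulate import write_genome

        d = tempfile.mkdtemp()
        write_genome(sim, os.path.join(d, "g.fa"), os.path.join(d, "a.gtf"))
        fasta = pyfaidx.Fasta(os.path.join(d, "g.fa"))
        introns = list(sim.introns.values())
        scorer = train_scorer_from_introns(introns, fasta)
        feats = pd.DataFrame(
            [dict(intron_id=x.intron_id, **vars(intron_features(x, fasta, scorer))) for x in introns]
        ).set_index("intron_id")
        # CLIP+ = suboptimal introns (full coupling), CLIP- = optimal
        plus = [x.intron_id for x in introns if sim.intron_class[x.intron_id] == "suboptimal"]
        minus = [x.intron_id for x in introns if sim.intron_class[x.intron_id] == "optimal"]
        out = compare_intron_groups(feats, plus, minus).set_index("feature")
        assert out.loc["length", "p_value"] < 0.01
        assert out.loc["length", "direction"] == "lower_in_clip_plus"
        assert out.loc["gc", "p_value"] < 0.01
        assert out.loc["gc", "direction"] == "higher_in_clip_plus"
        assert out.loc["ss5_score", "p_value"] < 0.01
        assert out.loc["ss5_score", "direction"] == "lower_in_clip_plus"
        assert out.loc["ss3_score", "p_value"] < 0.01
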