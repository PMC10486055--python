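"""Repertoire diversity estimators, clonality calls and IGH analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from immucluster.repertoire import (
    asymptotic_diversity,
    central_octamer,
    classify_repertoires,
    cluster_igh_cdr3,
    gini_index,
    isotype_composition,
    observed_diversity,
    read_clonotypes,
    ClonotypeTable,
)


def make_igh_table(records):
    """records: (cdr3, count) or (cdr3, count, isotype)."""
    rows = [{"cdr3_aa": r[0], "chain": "IGH",
             "c_segment": r[2] if len(r) > 2 else "IGHG1", "count": r[1]}
            for r in records]
    df = pd.DataFrame(rows)
    df["fraction"] = df["count"] / df["count"].sum()
    return ClonotypeTable(sample_id="t", records=df)


class TestObservedDiversity:
    def test_single_clone_degenerate(self):
        assert observed_diversity([7]) == (1, 0.0, 1.0)

    def test_uniform_closed_form(self):
        s, h, inv = observed_diversity([5, 5, 5, 5])
        assert s == 4
        assert h == pytest.approx(np.log(4), abs=1e-12)
        assert inv == pytest.approx(4.0, abs=1e-12)

    def test_matches_direct_evaluation(self):
        counts = np.array([1, 1, 2, 3])
        p = counts / counts.sum()
        _, h, inv = observed_diversity(counts)
        assert h == pytest.approx(-(p * np.log(p)).sum(), abs=1e-12)
        assert inv == pytest.approx(1 / (p**2).sum(), abs=1e-12)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            observed_diversity([])


class TestAsymptoticDiversity:
    def test_chao1_closed_form_with_doubletons(self):
        est = asymptotic_diversity([1, 1, 2, 3])
        # f1=2, f2=1, n=7: chao1 = 4 + (6/7) * 4/2
        assert est.chao1 == pytest.approx(4 + 6 / 7 * 2, abs=1e-12)
        assert (est.f1, est.f2, est.n) == (2, 1, 7)

    def test_chao1_bias_corrected_form_without_doubletons(self):
        est = asymptotic_diversity([1, 1, 1, 5])
        n, f1 = 8, 3
        assert est.chao1 == pytest.approx(4 + (n - 1) / n * f1 * (f1 - 1) / 2)

    def test_exclusion_too_few_clonotypes(self):
        est = asymptotic_diversity([5, 5])
        assert est.excluded and est.exclusion_reason == "too_few_clonotypes"
        assert est.chao1 is None and est.shannon_est is None

    def test_exclusion_all_equal_fractions(self):
        est = asymptotic_diversity([4, 4, 4])
        assert est.excluded and est.exclusion_reason == "all_equal_fractions"

    def test_partial_ties_do_not_exclude(self):
        est = asymptotic_diversity([4, 4, 2])
        assert not est.excluded

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            asymptotic_diversity([1.5, 2, 3])

    def test_asymptotic_shannon_recovers_uniform_population(self):
        # 2000 reads from 26 equally abundant clones
        rng = np.random.default_rng(0)
        counts = rng.multinomial(2000, np.full(26, 1 / 26))
        est = asymptotic_diversity(counts[counts > 0])
        assert abs(est.shannon_est - np.log(26)) < 0.05

    def test_estimator_corrects_undersampling_upward(self):
        rng = np.random.default_rng(1)
        counts = rng.multinomial(300, np.full(200, 1 / 200))
        est = asymptotic_diversity(counts[counts > 0])
        assert est.shannon_est > est.shannon_obs
        assert est.chao1 > est.s_obs

    @given(st.lists(st.integers(1, 50), min_size=3, max_size=30).filter(
        lambda c: len(set(c)) > 1))
    def test_invariants_and_order_independence(self, counts):
        est = asymptotic_diversity(counts)
        perm = asymptotic_diversity(counts[::-1])
        assert est.chao1 >= est.s_obs
        assert est.shannon_est >= est.shannon_obs - 1e-12
        assert est.simpson_inv_est >= 1.0
        assert est.chao1 == perm.chao1
        assert est.shannon_est == pytest.approx(perm.shannon_est, rel=1e-12)

    def test_rarefaction_never_increases_observed_richness(self):
        rng = np.random.default_rng(2)
        pop = rng.multinomial(5000, np.full(100, 0.01))
        reads = np.repeat(np.arange(100), pop)
        for frac in (0.5, 0.2, 0.05):
            sub = rng.choice(reads, size=int(len(reads) * frac), replace=False)
            assert len(np.unique(sub)) <= len(np.unique(reads))


class TestClassifyRepertoires:
    @staticmethod
    def frame(y, x):
        return pd.DataFrame({"shannon_est": y, "n_reads": x},
                            index=[f"s{i}" for i in range(len(y))])

    def test_collinear_points_all_typical(self):
        x = np.logspace(2, 4, 12)
        y = 10 ** (0.3 * np.log10(x) + 0.1)
        res = classify_repertoires(self.frame(y, x))
        assert (res.table["class"] == "typical").all()
        assert res.sigma == pytest.approx(0.0, abs=1e-12)

    def test_two_sigma_rule_flags_planted_outliers(self):
        x = np.logspace(2.5, 4, 40)
        y = 10 ** (0.3 * np.log10(x))
        y[5] /= 10 ** 1.0   # deep clonal outlier
        y[20] *= 10 ** 1.0  # polyclonal outlier
        res = classify_repertoires(self.frame(y, x))
        assert res.table["class"].iloc[5] == "clonal"
        assert res.table["class"].iloc[20] == "polyclonal"
        assert (res.table["class"] == "typical").sum() == 38

    def test_refit_after_removing_typical_matches_brute_force(self):
        rng = np.random.default_rng(3)
        x = np.logspace(2.5, 4, 30)
        y = 10 ** (0.3 * np.log10(x) + rng.normal(0, 0.05, 30))
        full = classify_repertoires(self.frame(y, x))
        dropped = classify_repertoires(self.frame(np.delete(y, 7),
                                                  np.delete(x, 7)))
        lx, ly = np.log10(np.delete(x, 7)), np.log10(np.delete(y, 7))
        slope, intercept = np.polyfit(lx, ly, 1)
        resid = ly - (slope * lx + intercept)
        sigma = np.sqrt((resid**2).sum() / (len(lx) - 2))
        assert dropped.sigma == pytest.approx(sigma, abs=1e-12)
        expected = np.where(resid < -2 * sigma, "clonal",
                            np.where(resid > 2 * sigma, "polyclonal", "typical"))
        assert list(dropped.table["class"]) == list(expected)

    def test_fewer_than_ten_samples_refused(self):
        with pytest.raises(ValueError, match="10"):
            classify_repertoires(self.frame(np.ones(5) * 2, np.ones(5) * 100))


class TestIsotypeComposition:
    def test_single_isotype(self):
        table = make_igh_table([("CARDYWAAAA", 5), ("CSSSYWAAAA", 3)])
        comp = isotype_composition(table)
        assert comp.loc["IGHG1", "clonotype_fraction"] == 1.0
        assert comp.loc["IGHG1", "read_fraction"] == 1.0

    def test_equal_reads_split(self):
        table = make_igh_table([("CARDYWAAAA", 4, "IGHM"), ("CSSSYWAAAA", 4, "IGHG1")])
        comp = isotype_composition(table)
        assert comp["read_fraction"].to_dict() == {"IGHG1": 0.5, "IGHM": 0.5}

    def test_no_igh_records_flagged_empty(self, caplog):
        df = pd.DataFrame({"cdr3_aa": ["CASSL"], "chain": ["TRB"],
                           "c_segment": [None], "count": [3], "fraction": [1.0]})
        table = ClonotypeTable("x", df)
        with caplog.at_level("INFO"):
            comp = isotype_composition(table)
        assert comp.empty


def brute_force_octamer_clusters(seqs_counts, min_count=3):
    """Exhaustive single-linkage over the Hamming<=1 octamer graph."""
    kept = {s: c for s, c in seqs_counts.items() if c >= min_count}
    seqs = sorted(kept)
    def octa(s):
        start = (len(s) - 8) // 2
        return s[start:start + 8]
    adj = {s: set() for s in seqs}
    for i, a in enumerate(seqs):
        for b in seqs[i + 1:]:
            if len(a) >= 8 and len(b) >= 8:
                if sum(x != y for x, y in zip(octa(a), octa(b))) <= 1:
                    adj[a].add(b)
                    adj[b].add(a)
    seen, clusters = set(), []
    for s in seqs:
        if s in seen:
            continue
        stack, comp = [s], set()
        while stack:
            cur = stack.pop()
            if cur in comp:
                continue
            comp.add(cur)
            stack.extend(adj[cur] - comp)
        seen |= comp
        clusters.append((frozenset(comp), sum(kept[m] for m in comp)))
    return set(clusters)


class TestIghClustering:
    def test_one_mismatch_joins(self):
        table = make_igh_table([("CARDYWAA", 5), ("CARDYWAV", 4)])
        res = cluster_igh_cdr3(table)
        assert len(res.clusters) == 1
        assert res.clusters[0][1] == 9

    def test_three_mismatches_separate(self):
        table = make_igh_table([("CARDYWAA", 5), ("CTRDYFAV", 4)])
        res = cluster_igh_cdr3(table)
        assert len(res.clusters) == 2

    def test_suboctamer_always_singleton(self):
        table = make_igh_table([("CARS", 7), ("CARSYWAA", 5), ("CARSYWAV", 6)])
        res = cluster_igh_cdr3(table)
        sizes = {cl[0]: cl[1] for cl in res.clusters}
        assert (("CARS",), 7) in res.clusters
        assert len(res.clusters) == 2

    def test_low_count_sequences_removed(self):
        table = make_igh_table([("CARDYWAA", 2), ("CSSSYWAA", 5), ("CCCCYWAA", 3),
                                ("CWWWYWAA", 4), ("CKKKYWAA", 6)])
        res = cluster_igh_cdr3(table)
        members = {s for cl in res.clusters for s in cl[0]}
        assert "CARDYWAA" not in members
        assert res.n_sequences_used == 4

    def test_three_or_fewer_sequences_excluded_from_gini(self):
        table = make_igh_table([("CARDYWAA", 5), ("CTTTYWRR", 4), ("CKKKYWGG", 9)])
        res = cluster_igh_cdr3(table)
        assert res.excluded and res.gini is None

    def test_central_octamer_left_bias(self):
        assert central_octamer("ABCDEFGH") == "ABCDEFGH"
        assert central_octamer("ABCDEFGHI") == "ABCDEFGH"
        assert central_octamer("XABCDEFGHI") == "ABCDEFGH"

    @given(st.data())
    def test_matches_brute_force_on_random_repertoires(self, data):
        aa = "ACDEFGHIKLMNPQRSTVWY"
        n = data.draw(st.integers(2, 50))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        seqs = {}
        base = "".join(rng.choice(list(aa), 12))
        for _ in range(n):
            if rng.random() < 0.5 and seqs:
                # mutate an existing sequence to create near neighbours
                src = list(seqs)[int(rng.integers(len(seqs)))]
                pos = int(rng.integers(len(src)))
                s = src[:pos] + str(rng.choice(list(aa))) + src[pos + 1:]
            else:
                s = "".join(rng.choice(list(aa), int(rng.integers(4, 16))))
            seqs[s] = int(rng.integers(1, 8))
        table = make_igh_table(list(seqs.items()))
        res = cluster_igh_cdr3(table)
        got = {(frozenset(m), size) for m, size in res.clusters}
        agg = table.records.groupby("cdr3_aa")["count"].sum().to_dict()
        assert got == brute_force_octamer_clusters(agg)


class TestGini:
    def test_perfect_equality(self):
        assert gini_index([5, 5, 5]) == pytest.approx(0.0, abs=1e-15)

    def test_two_point_example(self):
        # sum |xi - xj| over ordered pairs = 4; 2 n^2 mu = 2*4*2 = 16
        assert gini_index([1, 3]) == pytest.approx(0.25, abs=1e-15)

    def test_matches_pairwise_oracle(self, rng):
        x = rng.uniform(0.1, 10, size=40)
        n, mu = len(x), x.mean()
        brute = sum(abs(a - b) for a in x for b in x) / (2 * n * n * mu)
        assert gini_index(x) == pytest.approx(brute, abs=1e-12)

    @given(st.lists(st.floats(0.1, 100), min_size=1, max_size=40))
    def test_range_and_permutation_invariance(self, sizes):
        g = gini_index(sizes)
        assert 0 <= g <= 1 - 1 / len(sizes) + 1e-12
        assert gini_index(sorted(sizes, reverse=True)) == pytest.approx(g, abs=1e-12)

    def test_min_sequences_exclusion(self):
        assert gini_index([1, 2, 3], min_sequences=4) is None
        with pytest.raises(ValueError):
            gini_index([])


class TestReadClonotypes:
    def test_well_formed_file(self, tmp_path):
        path = tmp_path / "sample1.tsv"
        path.write_text(
            "cloneCount\tcloneFraction\taaSeqCDR3\tallVHitsWithScore\tallCHitsWithScore\n"
            "10\t0.5\tCASSLGQAYEQYF\tTRBV6-5*00(100)\t\n"
            "6\t0.3\tCARDTWGDYW\tIGHV3-23*00(90)\tIGHG1*00(50)\n"
            "4\t0.2\tCASSPGTDTQYF\tTRBV7-9*00(80)\t\n")
        table = read_clonotypes(path)
        assert table.sample_id == "sample1"
        assert len(table.records) == 3
        trb = table.chain("TRB")
        assert trb["fraction"].sum() == pytest.approx(1.0)
        igh = table.chain("IGH")
        assert igh["c_segment"].iloc[0] == "IGHG1"

    def test_zero_count_row_skipped(self, tmp_path, caplog):
        path = tmp_path / "s.tsv"
        path.write_text("cloneCount\taaSeqCDR3\n0\tCASSL\n5\tCASSF\n")
        with caplog.at_level("WARNING"):
            table = read_clonotypes(path)
        assert len(table.records) == 1

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("cloneCount\tnotCDR3\n5\tCASSL\n")
        with pytest.raises(ValueError, match="aaSeqCDR3"):
            read_clonotypes(path)
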