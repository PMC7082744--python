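"""Seed extraction, motif categories, Fisher's exact test and set integration."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mirscreen import integrate_seed as iseed
from mirscreen.integrate_seed import ContingencyTable2x2, MiRNARecord

# the two miRs reported as common to all three datasets, with their
# mature sequences (miRBase nomenclature)
SEQ_302D = "UAAGUGCUUCCAUGUUUGAGUGU"
SEQ_373 = "GAAGUGCUUCGAUUUUGGGGUGU"

rna = st.text(alphabet="ACGU", min_size=7, max_size=26)


class TestSeedExtraction:
    @pytest.mark.parametrize(
        "seq,expected",
        [(SEQ_302D, "AAGUGC"), (SEQ_373, "AAGUGC"), ("AAAAAAA", "AAAAAA")],
    )
    def test_positions_2_to_7(self, seq, expected):
        assert iseed.extract_seed(seq) == expected

    def test_dna_alphabet_normalized(self):
        assert iseed.extract_seed("gaagtgcttcga") == "AAGUGC"

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            iseed.extract_seed("AAGUGC")

    @given(rna)
    @settings(max_examples=200, derandomize=True)
    def test_seed_is_always_six_nt_and_prefix_window(self, seq):
        seed = iseed.extract_seed(seq)
        assert len(seed) == 6
        assert 2 in iseed.motif_position(seq, seed).starts


class TestMotifPosition:
    def test_match_at_two(self):
        assert iseed.motif_position(SEQ_302D, "AAGUGC").category == "pos2_7"

    def test_match_at_three(self):
        res = iseed.motif_position("CAAAGUGCUU", "AAGUGC")
        assert res.category == "pos3_8"
        assert res.starts == (3,)

    def test_absent(self):
        assert iseed.motif_position("UUUUUUUUUU", "AAGUGC").category == "absent"

    def test_other_position(self):
        assert iseed.motif_position("UUUUAAGUGCUU", "AAGUGC").category == "other_position"

    def test_position_two_takes_priority_over_three(self):
        res = iseed.motif_position("UAAAAAAAU", "AAAAAA")
        assert res.category == "pos2_7"
        assert set(res.starts) == {2, 3}

    def test_motif_validation(self):
        with pytest.raises(ValueError):
            iseed.motif_position("ACGUACGU", "ACGUACG")  # 7-mer
        with pytest.raises(ValueError):
            iseed.motif_position("ACGUACGU", "ACGUXN")


class TestReconcileNames:
    def test_sequence_match_across_alphabets(self):
        ref = [MiRNARecord("hsa-miR-373-3p", SEQ_373)]
        query = [MiRNARecord("lib-0001", "gaagtgcttcgattttggggtgt")]  # DNA, lowercase
        amap = iseed.reconcile_names(query, ref)
        assert amap.matches == {"lib-0001": ["hsa-miR-373-3p"]}
        assert amap.unmatched == []

    def test_novel_sequence_unmatched(self):
        ref = [MiRNARecord("hsa-miR-373-3p", SEQ_373)]
        amap = iseed.reconcile_names([MiRNARecord("x", "ACGUACGUACGUACGUACGU")], ref)
        assert amap.unmatched == ["x"]

    def test_ambiguous_many_to_one_flagged(self):
        ref = [MiRNARecord("name-a", SEQ_373), MiRNARecord("name-b", SEQ_373)]
        amap = iseed.reconcile_names([MiRNARecord("q", SEQ_373)], ref)
        assert sorted(amap.matches["q"]) == ["name-a", "name-b"]
        assert amap.ambiguous == ["q"]

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            iseed.reconcile_names([MiRNARecord("q", SEQ_373)], [])

    def test_fasta_roundtrip(self, tmp_path):
        path = tmp_path / "ref.fasta"
        iseed.write_fasta([MiRNARecord("a", SEQ_373), MiRNARecord("b", SEQ_302D)], path)
        back = iseed.read_fasta(path)
        assert [(r.name, r.sequence) for r in back] == [("a", SEQ_373), ("b", SEQ_302D)]


class TestFisherExact:
    def test_diagonal_table_enumeration(self):
        odds, p = iseed.fisher_exact(ContingencyTable2x2(5, 0, 0, 5))
        assert math.isinf(odds)
        assert p == pytest.approx(2 / 252)

    def test_flat_table_p_one(self):
        odds, p = iseed.fisher_exact(ContingencyTable2x2(1, 1, 1, 1))
        assert odds == 1.0
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_agreement_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 16, 4)
            if a + b + c + d == 0:
                continue
            ours = iseed.fisher_exact(ContingencyTable2x2(a, b, c, d))[1]
            ref = stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            iseed.fisher_exact(ContingencyTable2x2(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 0, 1)


def make_universe(n_carriers, n_total, seed=0):
    records, _ = __import__("mirscreen").synthgen.gen_library(
        n_total, n_carriers, "AAGUGC", rng_seed=seed
    )
    return records


class TestSeedEnrichment:
    def test_planted_enrichment_significant(self):
        records = make_universe(40, 1250, seed=1)
        carriers = [r.name for r in records if r.seed == "AAGUGC"]
        others = [r.name for r in records if r.seed != "AAGUGC"]
        hits = set(carriers[:25]) | set(others[:175])
        res = iseed.seed_enrichment(hits, records, "AAGUGC")
        assert (res.table.a, res.table.c) == (25, 15)
        assert res.pvalue < 0.01

    def test_zero_carriers_p_one(self):
        records = make_universe(0, 100, seed=2)
        res = iseed.seed_enrichment({records[0].name}, records, "AAGUGC")
        assert res.pvalue == 1.0
        assert math.isnan(res.odds_ratio)

    def test_hits_outside_universe_rejected(self):
        records = make_universe(5, 50, seed=3)
        with pytest.raises(ValueError):
            iseed.seed_enrichment({"not-a-mir"}, records)

    def test_invariant_to_universe_order(self):
        records = make_universe(10, 200, seed=4)
        hits = {r.name for r in records[:30]}
        a = iseed.seed_enrichment(hits, records)
        b = iseed.seed_enrichment(hits, list(reversed(records)))
        assert a.pvalue == b.pvalue and a.table == b.table

    def test_null_pvalues_are_superuniform(self):
        # the exact test is discrete, so null p-values are conservative
        # (stochastically larger than uniform) rather than exactly uniform
        rng = np.random.default_rng(5)
        records = make_universe(40, 1250, seed=5)
        names = [r.name for r in records]
        ps = []
        for _ in range(300):
            hits = rng.choice(names, size=200, replace=False)
            ps.append(iseed.seed_enrichment(hits, records).pvalue)
        ps = np.asarray(ps)
        for alpha in (0.01, 0.05, 0.2):
            assert (ps < alpha).mean() <= alpha + 0.03

    def test_anywhere_mode_counts_internal_matches(self):
        records = [
            MiRNARecord("a", "UUUUAAGUGCUUUU"),   # internal motif only
            MiRNARecord("b", "UAAGUGCUUUUUUU"),   # seed-position motif
            MiRNARecord("c", "UUUUUUUUUUUUUU"),
        ]
        res_seed = iseed.seed_enrichment({"a"}, records, mode="seed2_7")
        res_any = iseed.seed_enrichment({"a"}, records, mode="anywhere")
        assert res_seed.table.a == 0
        assert res_any.table.a == 1


class TestIntersectHits:
    def test_triple_intersection(self):
        member, counts = iseed.intersect_hits(
            {"s1": {"A", "B"}, "s2": {"B", "C"}, "s3": {"B"}}
        )
        assert iseed.intersection_members(member) == ["B"]
        assert counts["111"] == 1

    def test_printed_scores_scenario(self):
        # both reported miRs pass all three filters at their printed values
        rows = {
            "hsa-mir-302d-3p": {"mig": -1.06, "ecc": -1.36, "lfc": 1.36},
            "hsa-mir-373-3p": {"mig": -1.56, "ecc": -1.98, "lfc": 8.78},
        }
        mig_low = {m for m, v in rows.items() if v["mig"] < -1}
        ecc_low = {m for m, v in rows.items() if v["ecc"] < -1}
        high_e = {m for m, v in rows.items() if v["lfc"] > 1}
        member, _ = iseed.intersect_hits(
            {"migration": mig_low, "eccentricity": ecc_low, "ARCaPE_high": high_e}
        )
        assert iseed.intersection_members(member) == sorted(rows)

    def test_disjoint_sets(self):
        member, counts = iseed.intersect_hits({"a": {"X"}, "b": {"Y"}})
        assert iseed.intersection_members(member) == []
        assert counts == {"10": 1, "01": 1}

    def test_requires_two_sets(self):
        with pytest.raises(ValueError):
            iseed.intersect_hits({"only": {"A"}})


class TestPositionalGroupStats:
    def test_planted_group_ordering(self):
        records = [
            MiRNARecord("m1", "UAAGUGCUUCCAUGUUUGAG"),  # pos2_7
            MiRNARecord("m2", "CAAGUGCAUCCAUGUUUGAG"),  # pos2_7
            MiRNARecord("m3", "ACGUCGUACGUACGUACGUA"),  # absent
            MiRNARecord("m4", "ACGACGUACGUACGUACGAC"),  # absent
        ]
        scores = pd.DataFrame(
            {"screen": ["migration"] * 4,
             "mir_name": ["m1", "m2", "m3", "m4"],
             "z_avg": [-2.0, -1.8, 0.1, -0.1]}
        )
        out = iseed.positional_group_stats(scores, records)
        out = out.set_index("category")
        assert out.loc["pos2_7", "mean_z"] < out.loc["absent", "mean_z"]
        assert out.loc["pos2_7", "n"] == 2

    def test_single_member_group_mean_is_its_z(self):
        records = [MiRNARecord("m1", "UAAGUGCUUCCAUGUUUGAG")]
        scores = pd.DataFrame(
            {"screen": ["migration"], "mir_name": ["m1"], "z_avg": [-1.5]}
        )
        out = iseed.positional_group_stats(scores, records)
        assert out.loc[0, "mean_z"] == -1.5

    def test_all_absent_only_one_group(self):
        records = [MiRNARecord("m1", "ACGUCGUACGUACGUACGUA")]
        scores = pd.DataFrame(
            {"screen": ["migration"], "mir_name": ["m1"], "z_avg": [0.0]}
        )
        out = iseed.positional_group_stats(scores, records)
        assert list(out["category"]) == ["absent"]


class TestConsensusProfile:
    def test_reported_homology_positions_of_seed_family(self):
        profile, consensus = iseed.consensus_profile([SEQ_302D, SEQ_373])
        for pos, base in {10: "C", 13: "U", 15: "U", 20: "G"}.items():
            assert consensus[pos] == base
            assert profile.loc[base, pos] == 1.0

    def test_identical_sequences_full_consensus(self):
        _, consensus = iseed.consensus_profile([SEQ_373, SEQ_373])
        assert len(consensus) == len(SEQ_373)

    def test_frequencies_sum_to_one_per_position(self):
        profile, _ = iseed.consensus_profile([SEQ_302D, SEQ_373, SEQ_302D])
        assert np.allclose(profile.sum(axis=0), 1.0)

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            iseed.consensus_profile([SEQ_373])


class TestTargetRanking:
    def test_counts_distinct_mirs_per_gene(self):
        pairs = pd.DataFrame(
            {"mir": ["m1", "m2", "m1"], "gene": ["G1", "G1", "G2"]}
        )
        out = iseed.target_ranking(pairs, {"m1", "m2"})
        assert list(out["gene"]) == ["G1", "G2"]
        assert list(out["n_mirs"]) == [2, 1]

    def test_duplicates_count_once_and_ties_alphabetical(self):
        pairs = pd.DataFrame(
            {"mir": ["m1", "m1", "m1", "m2"], "gene": ["G2", "G2", "G1", "G1"]}
        )
        out = iseed.target_ranking(pairs, {"m1", "m2"})
        assert list(out["gene"]) == ["G1", "G2"]

    def test_empty_subset_gives_empty_ranking(self):
        pairs = pd.DataFrame({"mir": ["m1"], "gene": ["G1"]})
        out = iseed.target_ranking(pairs, {"zzz"}, top_k=5)
        assert len(out) == 0
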