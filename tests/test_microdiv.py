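"""Pairwise identity, greedy OTU clustering and microdiversity statistics."""

import numpy as np
import pandas as pd
import pytest

from habniche import (
    greedy_otu_cluster,
    microdiversity_by_occurrence,
    nearest_taxon_closeness,
    pairwise_identity,
)
from habniche.microdiv import intra_otu_counts, otu_occurrence


def _needleman_wunsch_identity(a, b):
    """Independent DP oracle: match 1, mismatch 0, linear gap -1; identity of
    a traced-back optimal alignment (matches / columns)."""
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        score[i][0] = -i
    for j in range(1, m + 1):
        score[0][j] = -j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1][j - 1] + (1 if a[i - 1] == b[j - 1] else 0)
            score[i][j] = max(diag, score[i - 1][j] - 1, score[i][j - 1] - 1)
    # traceback preferring diagonal moves
    i, j, matches, cols = n, m, 0, 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i][j] == score[i - 1][j - 1] + (
            1 if a[i - 1] == b[j - 1] else 0
        ):
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and score[i][j] == score[i - 1][j] - 1:
            i -= 1
        else:
            j -= 1
        cols += 1
    return matches / cols


def _mutate(rng, seq, n_sub):
    s = list(seq)
    for pos in rng.choice(len(s), size=n_sub, replace=False):
        s[pos] = rng.choice([b for b in "ACGT" if b != s[pos]])
    return "".join(s)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        s = "ACGT" * 25
        assert pairwise_identity(s, s) == 1.0

    def test_three_substitutions_in_hundred(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=100))
        b = _mutate(rng, a, 3)
        assert pairwise_identity(a, b) == pytest.approx(0.97)

    def test_symmetry(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=40))
        b = "".join(rng.choice(list("ACGT"), size=35))
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_matches_dp_oracle_on_substituted_pairs(self, rng):
        """Substitution-only pairs of length <= 30 vs the reference DP."""
        for _ in range(10):
            n = int(rng.integers(10, 31))
            a = "".join(rng.choice(list("ACGT"), size=n))
            b = _mutate(rng, a, int(rng.integers(0, max(1, n // 10) + 1)))
            assert pairwise_identity(a, b) == pytest.approx(
                _needleman_wunsch_identity(a, b)
            )


class TestGreedyClustering:
    def test_hand_simulated_greedy_pass(self, rng):
        """a joins b (0.98 >= t); c starts its own OTU (0.90 < t to both)."""
        base = "".join(rng.choice(list("ACGT"), size=100))
        seqs = {
            "a": base,
            "b": _mutate(rng, base, 2),   # 0.98 to a
            "c": _mutate(rng, base, 10),  # 0.90 to a
        }
        abund = {"a": 30, "b": 20, "c": 10}
        out = greedy_otu_cluster(seqs, abund, threshold=0.97).set_index("asv")
        assert out.loc["a", "otu"] == "a" and out.loc["a", "is_centroid"]
        assert out.loc["b", "otu"] == "a"
        assert out.loc["c", "is_centroid"]

    def test_identical_sequences_one_otu(self):
        seqs = {f"s{i}": "ACGT" * 10 for i in range(4)}
        out = greedy_otu_cluster(seqs, {k: 1 for k in seqs})
        assert out["otu"].nunique() == 1

    def test_threshold_one_all_distinct_singletons(self, rng):
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACGT"), size=50)) for i in range(5)
        }
        out = greedy_otu_cluster(seqs, {k: 1 for k in seqs}, threshold=1.0)
        assert out["is_centroid"].all()

    def test_membership_matches_naive_reimplementation(self, rng):
        """Package clustering vs an independent greedy pass built on the DP
        oracle, over randomized lineage families."""
        for trial in range(8):
            seqs, abund = {}, {}
            for fam in range(int(rng.integers(2, 5))):
                anc = "".join(rng.choice(list("ACGT"), size=60))
                for v in range(int(rng.integers(1, 4))):
                    sid = f"f{fam}v{v}"
                    seqs[sid] = anc if v == 0 else _mutate(rng, anc, 1)
                    abund[sid] = float(rng.integers(1, 100))
            order = sorted(seqs, key=lambda i: (-abund[i], i))
            centroids, naive = [], {}
            for sid in order:
                for cid in centroids:
                    if _needleman_wunsch_identity(seqs[sid], seqs[cid]) >= 0.97:
                        naive[sid] = cid
                        break
                else:
                    centroids.append(sid)
                    naive[sid] = sid
            out = greedy_otu_cluster(seqs, abund, threshold=0.97)
            assert dict(zip(out["asv"], out["otu"])) == naive

    def test_invariant_to_input_order(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=80))
        seqs = {f"s{i}": _mutate(rng, base, i) for i in range(6)}
        abund = {f"s{i}": 10 - i for i in range(6)}
        a = greedy_otu_cluster(seqs, abund)
        rev = dict(reversed(list(seqs.items())))
        b = greedy_otu_cluster(rev, abund)
        pd.testing.assert_frame_equal(a, b)

    def test_members_at_least_threshold_to_centroid(self, small_sim):
        from habniche import simulate_sequences

        cfg, _, _, truth = small_sim
        seqs, _ = simulate_sequences(truth, cfg)
        some = dict(list(seqs.items())[:60])
        abund = {s: (2.0 if ".v" not in s else 1.0) for s in some}
        out = greedy_otu_cluster(some, abund, threshold=0.97)
        for row in out.itertuples():
            assert pairwise_identity(some[row.asv], some[row.otu]) >= 0.97

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            greedy_otu_cluster({"a": "ACGT"}, {"a": 1}, threshold=1.5)


class TestNearestTaxonCloseness:
    def test_direct_value(self):
        d = pd.DataFrame(
            [[0, 0.1, 0.4], [0.1, 0, 0.5], [0.4, 0.5, 0]],
            index=list("abc"), columns=list("abc"),
        )
        out = nearest_taxon_closeness(d)
        assert out.loc["a", "nearest_distance"] == pytest.approx(0.1)
        assert out.loc["a", "closeness"] == pytest.approx(-np.log(0.1))

    def test_zero_distance_floored_to_half_min_positive(self):
        d = pd.DataFrame(
            [[0, 0.0, 0.02], [0.0, 0, 0.02], [0.02, 0.02, 0]],
            index=list("abc"), columns=list("abc"),
        )
        out = nearest_taxon_closeness(d)
        assert out.loc["a", "closeness"] == pytest.approx(-np.log(0.01))

    def test_unit_distance_zero_closeness(self):
        d = pd.DataFrame([[0, 1.0], [1.0, 0]], index=list("ab"), columns=list("ab"))
        out = nearest_taxon_closeness(d)
        assert out["closeness"].tolist() == pytest.approx([0.0, 0.0])

    def test_antitone_in_distance(self, rng):
        n = 6
        m = rng.uniform(0.05, 1.0, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        d = pd.DataFrame(m, index=list("abcdef"), columns=list("abcdef"))
        out = nearest_taxon_closeness(d)
        order_d = out["nearest_distance"].rank()
        order_c = out["closeness"].rank(ascending=False)
        assert (order_d == order_c).all()

    def test_log_base_10(self):
        d = pd.DataFrame([[0, 0.1], [0.1, 0]], index=list("ab"), columns=list("ab"))
        out = nearest_taxon_closeness(d, log_base=10)
        assert out.loc["a", "closeness"] == pytest.approx(1.0)

    def test_single_taxon_rejected(self):
        d = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError):
            nearest_taxon_closeness(d)


class TestMicrodiversityByOccurrence:
    def test_all_singletons_no_differences(self):
        values = pd.Series([1] * 12)
        occ = pd.Series([1, 1, 1, 2, 2, 2, 3, 3, 3, 4, 4, 4])
        res = microdiversity_by_occurrence(values, occ)
        assert (res["summary"]["mean"] == 1).all()
        assert (res["pairwise"]["p_adj"] > 0.05).all()
        letters = set(res["letters"].values())
        assert len(letters) == 1

    def test_planted_gradient_detected(self, rng):
        occ = pd.Series(rng.integers(1, 5, size=200))
        values = occ * 2 + rng.normal(0, 0.5, size=200)
        res = microdiversity_by_occurrence(values, occ)
        assert res["spearman"]["rho"] > 0.5
        assert res["spearman"]["p"] < 1e-6

    def test_sparse_levels_kept_in_summary_not_tests(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0, 10.0])
        occ = pd.Series([1, 1, 2, 2, 3])  # level 3 has one observation
        res = microdiversity_by_occurrence(values, occ)
        assert 3 in res["summary"]["occurrence"].values
        tested = set(res["pairwise"][["level_a", "level_b"]].to_numpy().ravel())
        assert 3 not in tested

    def test_otu_helpers(self):
        asg = pd.DataFrame(
            {
                "asv": ["a", "b", "c", "d"],
                "otu": ["a", "a", "c", "c"],
                "is_centroid": [True, False, True, False],
                "identity": [1.0, 0.99, 1.0, 0.98],
            }
        )
        counts = intra_otu_counts(asg)
        assert counts.to_dict() == {"a": 2, "c": 2}
        occ = otu_occurrence(asg, pd.Series({"a": 1, "b": 3, "c": 2, "d": 1}))
        assert occ.to_dict() == {"a": 3, "c": 2}
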