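"""Change classification, neighbor selection, lists, and rating hygiene."""

import numpy as np
import pandas as pd
import pytest

from chronolex import (
    AlignedSeries,
    DecadeEmbeddings,
    DriftConfig,
    build_counterbalance_lists,
    build_stimulus_set,
    classify_change,
    clean_ratings,
    dedupe_pairs,
    nearest_neighbors,
    sample_non_neighbors,
    simulate_diachronic_embeddings,
    subsample_ratings,
)
from chronolex.stimuli import select_targets


def _two_decade_series(vectors_1950, vectors_1990, words):
    return AlignedSeries(
        [
            DecadeEmbeddings(1950, words, np.asarray(vectors_1950, dtype=float)),
            DecadeEmbeddings(1990, words, np.asarray(vectors_1990, dtype=float)),
        ],
        aligned=True,
        reference_decade=1990,
    )


class TestClassifyChange:
    def _series_with_sims(self, sims):
        words = [f"w{i}" for i in range(len(sims))]
        v50 = [[1.0, 0.0]] * len(sims)
        v90 = [[s, np.sqrt(1 - s * s)] for s in sims]
        return _two_decade_series(v50, v90, words), words

    def test_threshold_sides_and_boundary(self):
        series, words = self._series_with_sims([0.21, 0.71, 0.35])
        with pytest.warns(UserWarning, match="threshold"):
            out = classify_change(series, words)
        by_word = {t.word: t for t in out}
        assert by_word["w0"].change_status == "changed"
        assert by_word["w0"].self_sim == pytest.approx(0.21)
        assert by_word["w1"].change_status == "unchanged"
        assert "w2" not in by_word  # exactly at 0.35 left unassigned

    def test_invariant_to_common_orthogonal_transform(self, rng):
        words = [f"w{i}" for i in range(10)]
        a = rng.normal(size=(10, 4))
        b = rng.normal(size=(10, 4))
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        plain = classify_change(_two_decade_series(a, b, words), words)
        rotated = classify_change(_two_decade_series(a @ q, b @ q, words), words)
        for t1, t2 in zip(plain, rotated):
            assert t1.change_status == t2.change_status
            assert t1.self_sim == pytest.approx(t2.self_sim, abs=1e-10)

    def test_unaligned_refused(self, rng):
        words = ["a", "b", "c"]
        s = AlignedSeries(
            [
                DecadeEmbeddings(1950, words, rng.normal(size=(3, 2))),
                DecadeEmbeddings(1990, words, rng.normal(size=(3, 2))),
            ],
            aligned=False,
        )
        with pytest.raises(ValueError, match="align"):
            classify_change(s, words)


class TestSelectTargets:
    def test_ranking_by_extremity(self):
        from chronolex.stimuli import TargetWord

        cands = [
            TargetWord("most_changed", "changed", 0.05),
            TargetWord("less_changed", "changed", 0.30),
            TargetWord("most_stable", "unchanged", 0.95),
            TargetWord("less_stable", "unchanged", 0.50),
        ]
        out = select_targets(cands, n_changed=1, n_unchanged=1)
        assert [t.word for t in out] == ["most_changed", "most_stable"]


class TestNearestNeighbors:
    def test_duplicate_vector_ranks_first(self):
        emb = DecadeEmbeddings(
            1990,
            ["t", "twin", "far", "mid"],
            np.array([[1, 0], [2, 0], [0, 1], [1, 1]], dtype=float),
        )
        assert nearest_neighbors(emb, "t", k=2) == ["twin", "mid"]

    def test_matches_brute_force_oracle(self, rng):
        vecs = rng.normal(size=(12, 5))
        words = [f"w{i:02d}" for i in range(12)]
        emb = DecadeEmbeddings(1990, words, vecs)
        normed = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
        for word in words[:4]:
            i = words.index(word)
            sims = {w: float(normed[i] @ normed[j]) for j, w in enumerate(words) if j != i}
            oracle = sorted(sims, key=lambda w: (-sims[w], w))[:5]
            assert nearest_neighbors(emb, word, k=5) == oracle

    def test_exact_ties_broken_lexicographically(self):
        emb = DecadeEmbeddings(
            1990,
            ["t", "zeta", "alpha", "other"],
            np.array([[1, 0], [1, 1], [2, 2], [0, 1]], dtype=float),
        )
        # zeta and alpha have identical cosine to t
        assert nearest_neighbors(emb, "t", k=2) == ["alpha", "zeta"]

    def test_k_too_large(self):
        emb = DecadeEmbeddings(1990, ["a", "b"], np.eye(2))
        with pytest.raises(ValueError, match="vocabulary"):
            nearest_neighbors(emb, "a", k=2)


class TestSampleNonNeighbors:
    def test_exact_complement_returned(self):
        out = sample_non_neighbors(["a", "b", "c", "d"], "a", {"b"}, k=2, seed=0)
        assert sorted(out) == ["c", "d"]

    def test_never_intersects_excluded(self, rng):
        vocab = [f"w{i}" for i in range(30)]
        excluded = set(vocab[5:15])
        for seed in range(200):
            out = sample_non_neighbors(vocab, "w0", excluded, k=5, seed=seed)
            assert not set(out) & excluded and "w0" not in out

    def test_seed_determinism_and_too_small_complement(self):
        vocab = [f"w{i}" for i in range(20)]
        a = sample_non_neighbors(vocab, "w0", set(vocab[1:5]), k=6, seed=4)
        b = sample_non_neighbors(vocab, "w0", set(vocab[1:5]), k=6, seed=4)
        assert a == b
        with pytest.raises(ValueError, match="complement"):
            sample_non_neighbors(vocab[:5], "w0", set(vocab[1:4]), k=3, seed=0)


@pytest.fixture(scope="module")
def stimulus_series():
    """A 1950-1990 drift axis sized so 30+30 targets survive the threshold."""
    return simulate_diachronic_embeddings(
        DriftConfig(n_words=120, n_changed=55, first_decade=1950, n_decades=5, seed=9)
    )


@pytest.fixture(scope="module")
def small_stimulus_set(stimulus_series):
    return build_stimulus_set(
        stimulus_series, n_changed=30, n_unchanged=30, k_neighbors=4,
        k_non_neighbors=4, seed=1,
    )


class TestStimulusBuildAndLists:
    def test_pair_inventory_per_target(self, small_stimulus_set):
        for word, by_type in small_stimulus_set.pairs.items():
            assert len(by_type["n1950"]) == 4
            assert len(by_type["n1990"]) == 4
            assert len(by_type["non_neighbor"]) == 4
            assert word not in {p for v in by_type.values() for p in v}

    def test_list_audit(self, small_stimulus_set):
        # 60 targets x 4 appearances = 240 slots over 16 lists = 15 targets each
        lists = build_counterbalance_lists(small_stimulus_set, n_lists=16, seed=0)
        per_list = lists.groupby("list_id").agg(
            n_pairs=("partner", "size"), n_targets=("target", "nunique")
        )
        assert (per_list["n_pairs"] == 45).all()  # 15 targets x 3 pair types
        assert (per_list["n_targets"] == 15).all()
        changed = (
            lists[lists.change_status == "changed"].groupby("list_id")["target"].nunique()
        )
        assert set(changed.unique()) <= {7, 8}  # 30 x 4 / 16 = 7.5 per list
        # coverage: every constructed partner appears in at least one list
        covered = lists.groupby(["target", "pair_type"])["partner"].nunique()
        assert (covered == 4).all()

    def test_incompatible_list_count_rejected(self, small_stimulus_set):
        with pytest.raises(ValueError, match="evenly"):
            build_counterbalance_lists(small_stimulus_set, n_lists=17, seed=0)

    def test_deterministic_given_seed(self, small_stimulus_set):
        a = build_counterbalance_lists(small_stimulus_set, n_lists=16, seed=5)
        b = build_counterbalance_lists(small_stimulus_set, n_lists=16, seed=5)
        pd.testing.assert_frame_equal(a, b)


def _rating_rows(participants):
    rows = []
    for pid, catch, duration in participants:
        rows.append(
            {
                "participant_id": pid,
                "cohort": "YA",
                "target": "t",
                "partner": "p",
                "pair_type": "n1950",
                "rating": 3,
                "catch_score": catch,
                "duration": duration,
            }
        )
    return pd.DataFrame(rows)


class TestCleanRatings:
    def test_catch_and_duration_filters(self):
        df = _rating_rows(
            [("ok", 5, 10.0), ("lowcatch", 4, 10.0), ("fast", 5, 4.0), ("slow_ok", 5, 4.01)]
        )
        out, report = clean_ratings(df)
        kept = set(out["participant_id"])
        assert kept == {"ok", "slow_ok"}  # duration exactly 4.0 is excluded
        assert report["excluded_catch"] == 1
        assert report["excluded_duration"] == 1

    def test_all_pass_identity(self):
        df = _rating_rows([("a", 5, 9.0), ("b", 5, 8.0)])
        out, report = clean_ratings(df)
        assert len(out) == len(df) and report["kept_participants"] == 2


class TestDedupePairs:
    def _records(self, pairs):
        return pd.DataFrame(
            [
                {
                    "participant_id": f"p{i}",
                    "target": t,
                    "partner": p,
                    "pair_type": ptype,
                    "rating": 3,
                }
                for i, (t, p, ptype) in enumerate(pairs)
            ]
        )

    def test_no_overlap_identity(self):
        df = self._records([("t", "a", "n1950"), ("t", "b", "n1990")])
        assert len(dedupe_pairs(df)) == 2

    def test_shared_neighbor_keeps_first_listed_type(self):
        df = self._records([("t", "a", "n1950"), ("t", "a", "n1990")])
        out = dedupe_pairs(df)
        assert len(out) == 1 and out.iloc[0]["pair_type"] == "n1950"

    def test_surviving_count_matches_enumeration_oracle(self, rng):
        # targets with partially overlapping 1950/1990 neighbor sets
        pairs = []
        for t in range(12):
            n50 = [f"t{t}_n{i}" for i in range(5)]
            overlap = int(rng.integers(0, 3))
            n90 = n50[:overlap] + [f"t{t}_m{i}" for i in range(5 - overlap)]
            pairs += [(f"t{t}", p, "n1950") for p in n50]
            pairs += [(f"t{t}", p, "n1990") for p in n90]
        df = self._records(pairs)
        out = dedupe_pairs(df)
        oracle = len({(t, p) for t, p, _ in pairs})
        assert len(out) == oracle


class TestSubsampleRatings:
    def _df(self, counts):
        rows = []
        for (t, p, cohort), n in counts.items():
            for i in range(n):
                rows.append(
                    {
                        "participant_id": f"{cohort}{i}",
                        "cohort": cohort,
                        "target": t,
                        "partner": p,
                        "rating": i % 7,
                    }
                )
        return pd.DataFrame(rows)

    def test_exact_counts_retained_and_downsampled(self):
        df = self._df({("t", "a", "YA"): 5, ("t", "a", "OA"): 8})
        out = subsample_ratings(df, per_cohort=5, seed=0)
        assert len(out) == 10
        assert (out.groupby("cohort").size() == 5).all()

    def test_output_size_forced_arithmetic(self):
        counts = {}
        for t in range(6):
            counts[(f"t{t}", "x", "YA")] = 7
            counts[(f"t{t}", "x", "OA")] = 6
        out = subsample_ratings(self._df(counts), per_cohort=5, seed=1)
        assert len(out) == 10 * 6

    def test_undersampled_pair_raises_or_drops(self):
        df = self._df({("t", "a", "YA"): 3, ("t", "a", "OA"): 5})
        with pytest.raises(ValueError, match="pairs have"):
            subsample_ratings(df, per_cohort=5, seed=0)
        with pytest.warns(UserWarning, match="dropping"):
            out = subsample_ratings(df, per_cohort=5, seed=0, on_short="drop")
        assert len(out) == 0
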