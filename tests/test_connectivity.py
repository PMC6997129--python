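"""KS enrichment score, therapeutic score, drug-drug connectivity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import kernelsig as ks
from kernelsig.connectivity import (
    DrugInstanceProfile,
    ProfileError,
    SignatureMismatchError,
    instance_score_table,
    read_instances_long,
    read_instances_rank_matrix,
    write_instances_long,
    write_instances_rank_matrix,
)
from kernelsig.gene_classes import DiseaseSignature

from conftest import es_bruteforce


def profile(genes, name="d", iid="i1"):
    return DrugInstanceProfile(instance_id=iid, drug_name=name, ranked_genes=tuple(genes))


class TestQueryPositions:
    def test_direct_lookup(self):
        prof = profile(["g1", "g2", "g3", "g4", "g5"])
        positions, dropped = ks.query_positions({"g2", "g5"}, prof)
        assert positions == (2, 5) and dropped == 0

    def test_whole_universe(self):
        prof = profile([f"g{i}" for i in range(1, 6)])
        positions, _ = ks.query_positions(prof.ranked_genes, prof)
        assert positions == (1, 2, 3, 4, 5)

    def test_total_mismatch_is_error(self):
        with pytest.raises(SignatureMismatchError):
            ks.query_positions({"g9"}, profile(["g1", "g2", "g3", "g4", "g5"]))

    def test_partial_mismatch_drops_and_counts(self):
        positions, dropped = ks.query_positions(
            {"g2", "gX"}, profile(["g1", "g2", "g3"])
        )
        assert positions == (2,) and dropped == 1


class TestComputeES:
    @pytest.mark.parametrize(
        "positions,n,a,b,es",
        [
            ([1, 2], 10, 0.8, 0.1, 0.8),
            ([9, 10], 10, 0.0, 0.9, -0.9),
            ([1, 10], 10, 0.4, 0.5, -0.5),
        ],
    )
    def test_hand_enumerated_examples(self, positions, n, a, b, es):
        r = ks.compute_es(positions, n)
        assert r.a == pytest.approx(a)
        assert r.b == pytest.approx(b)
        assert r.es == pytest.approx(es)

    def test_exhaustive_agreement_with_bruteforce_oracle(self):
        """Implementation == term-by-term oracle for every non-empty position
        subset of every universe with n <= 12."""
        for n in range(2, 13):
            for m in range(1, n + 1):
                for positions in itertools.combinations(range(1, n + 1), m):
                    r = ks.compute_es(positions, n)
                    a, b, es = es_bruteforce(positions, n)
                    assert r.a == pytest.approx(a, abs=1e-12)
                    assert r.b == pytest.approx(b, abs=1e-12)
                    assert r.es == pytest.approx(es, abs=1e-12)
                    assert abs(r.es) <= 1.0

    @pytest.mark.parametrize("m,n", [(1, 5), (3, 10), (5, 50), (20, 1000)])
    def test_concentration_extremes(self, m, n):
        top = ks.compute_es(list(range(1, m + 1)), n)
        assert top.es == pytest.approx(1 - m / n)
        bottom = ks.compute_es(list(range(n - m + 1, n + 1)), n)
        assert bottom.es == pytest.approx(-(n - m + 1) / n)

    @given(st.data())
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_reversal_antisymmetry(self, data):
        """Reversing a profile flips the score: es(reversed) = -es within
        1/m - 1/n.

        Reversal maps the running maxima as a' = b - 1/n, b' = a + 1/n, so
        the flip is exact to O(1/n) whenever one maximum dominates by more
        than 2/n.  Near-symmetric position sets (|a - b| <= 2/n, e.g. {1, n},
        which is its own reversal) are excluded: there the score's sign is
        decided by the tie-break, not the data.  Tested at m <= n/4 where the
        stated tolerance exceeds the 1/n discrepancy.
        """
        from hypothesis import assume

        n = data.draw(st.integers(8, 400))
        m = data.draw(st.integers(1, max(1, n // 4)))
        positions = sorted(
            data.draw(
                st.lists(st.integers(1, n), min_size=m, max_size=m, unique=True)
            )
        )
        fwd = ks.compute_es(positions, n)
        assume(abs(fwd.a - fwd.b) > 2 / n + 1e-9)
        rev = ks.compute_es(sorted(n + 1 - p for p in positions), n).es
        assert abs(rev + fwd.es) <= 1 / m - 1 / n + 1e-12

    def test_depends_only_on_position_set(self):
        assert ks.compute_es((2, 5, 7), 20) == ks.compute_es([2, 5, 7], 20)

    @pytest.mark.parametrize("positions", [[5, 2], [0, 3], [3, 11], []])
    def test_invalid_positions_rejected(self, positions):
        with pytest.raises(ValueError):
            ks.compute_es(positions, 10)


class TestInstanceAndDrugScores:
    def test_window_placed_signature(self):
        genes = [f"g{i}" for i in range(1, 11)]
        prof = profile(genes)
        sig = DiseaseSignature(up=("g1", "g2"), down=("g9", "g10"))
        s = ks.score_instance(sig, prof)
        assert s.es_up == pytest.approx(0.8)
        assert s.es_down == pytest.approx(-0.9)

    def test_order_within_signature_lists_is_irrelevant(self):
        genes = [f"g{i}" for i in range(1, 11)]
        prof = profile(genes)
        s1 = ks.score_instance(DiseaseSignature(("g1", "g4"), ("g9", "g7")), prof)
        s2 = ks.score_instance(DiseaseSignature(("g4", "g1"), ("g7", "g9")), prof)
        assert (s1.es_up, s1.es_down) == (s2.es_up, s2.es_down)

    def test_empty_matched_side_names_the_side(self):
        prof = profile(["g1", "g2", "g3", "g4"])
        with pytest.raises(SignatureMismatchError, match="down"):
            ks.score_instance(DiseaseSignature(up=("g1",), down=("zz",)), prof)

    def test_ts_is_mean_of_instance_differences(self):
        genes = [f"g{i}" for i in range(1, 11)]
        sig = DiseaseSignature(up=("g1", "g2"), down=("g9", "g10"))
        p1 = profile(genes, iid="i1")  # es_up 0.8, es_down -0.9
        rev = profile(list(reversed(genes)), iid="i2")  # sides swap
        ds = ks.therapeutic_score(sig, [p1, rev])
        s1 = ks.score_instance(sig, p1)
        s2 = ks.score_instance(sig, rev)
        expected = ((s1.es_up - s1.es_down) + (s2.es_up - s2.es_down)) / 2
        assert ds.ts == pytest.approx(expected)
        assert ds.k == 2
        # permuting instance order changes nothing
        assert ks.therapeutic_score(sig, [rev, p1]).ts == pytest.approx(ds.ts)

    def test_equal_components_cancel(self):
        # positions {2,9} and {4,7} in a 10-gene list both give es = -0.4
        genes = [f"g{i}" for i in range(1, 11)]
        sig = DiseaseSignature(up=("g2", "g9"), down=("g4", "g7"))
        prof = profile(genes)
        s = ks.score_instance(sig, prof)
        assert s.es_up == pytest.approx(s.es_down) == pytest.approx(-0.4)
        assert ks.therapeutic_score(sig, [prof]).ts == pytest.approx(0.0)

    def test_cmap_zeroing_flag(self):
        genes = [f"g{i}" for i in range(1, 11)]
        # both sides at the top: es_up and es_down share a sign
        sig = DiseaseSignature(up=("g1", "g2"), down=("g3", "g4"))
        prof = profile(genes)
        plain = ks.therapeutic_score(sig, [prof], cmap_zeroing=False)
        zeroed = ks.therapeutic_score(sig, [prof], cmap_zeroing=True)
        s = plain.instance_scores[0]
        assert s.es_up * s.es_down > 0
        assert plain.ts != 0.0
        assert zeroed.ts == 0.0


class TestScoreAllDrugs:
    def test_grouping(self, study_dataset):
        sig = study_dataset.signature
        library = study_dataset.instances[:6]  # 3 drugs x 2 instances
        scores, unmatched = ks.score_all_drugs(sig, library)
        assert len(scores) == 3
        assert (scores["k"] == 2).all()
        assert unmatched == []
        detail = instance_score_table(scores)
        assert len(detail) == 6

    def test_unmatched_drugs_reported_not_dropped(self):
        sig = DiseaseSignature(up=("g1",), down=("g2",))
        good = profile(["g1", "g2", "g3"], name="good")
        alien = profile(["x1", "x2", "x3"], name="alien")
        scores, unmatched = ks.score_all_drugs(sig, [good, alien])
        assert list(scores["drug_name"]) == ["good"]
        assert unmatched == ["alien"]

    def test_null_drugs_center_at_zero(self):
        """Mean TS over 200 uniform-permutation drugs stays within 0.05."""
        cfg = ks.SimulationConfig(seed=21)
        universe = cfg.gene_universe()
        sig = DiseaseSignature(
            up=tuple(universe[:10]), down=tuple(universe[10:20])
        )
        lib_cfg = ks.default_drug_library_config(
            seed=21, n_reversal=0, n_mimic=0, n_null=200, n_instances=1
        )
        library = ks.gen_drug_instances(universe, lib_cfg, sig)
        scores, _ = ks.score_all_drugs(sig, library)
        assert abs(scores["ts"].mean()) < 0.05

    def test_planted_reversal_drugs_take_the_most_negative_ranks(self):
        """5 reversal drugs at s=0.05 among 100 drugs occupy the 5 lowest TS
        ranks in >= 9/10 seeds."""
        hits = 0
        for seed in range(10):
            ds = ks.generate_dataset(ks.SimulationConfig(seed=seed))
            scores, _ = ks.score_all_drugs(ds.signature, ds.instances)
            reversal = {d for d, m in ds.planted_drugs.items() if m == "reversal"}
            lowest = set(scores.nsmallest(len(reversal), "ts")["drug_name"])
            hits += lowest == reversal
        assert hits >= 9


class TestDrugQuerySignature:
    def test_single_instance_read_off(self):
        prof = profile(["g3", "g1", "g4", "g6", "g2", "g5"])
        sig = ks.drug_query_signature([prof], top_n=2)
        assert sig.up == ("g3", "g1")
        assert sig.down == ("g2", "g5")

    def test_mirror_instances_tie_break_lexicographic(self):
        genes = ["g1", "g2", "g3", "g4"]
        p1 = profile(genes, iid="i1")
        p2 = profile(list(reversed(genes)), iid="i2")
        with pytest.warns(UserWarning, match="tie"):
            sig = ks.drug_query_signature([p1, p2], top_n=1)
        assert sig.up == ("g1",)   # all mean positions tie at (n+1)/2
        assert sig.down == ("g4",)

    def test_half_split_covers_universe(self):
        prof = profile([f"g{i}" for i in range(1, 9)])
        sig = ks.drug_query_signature([prof], top_n=4)
        assert set(sig.up) | set(sig.down) == set(prof.ranked_genes)

    def test_oversized_top_n_rejected(self):
        with pytest.raises(ValueError):
            ks.drug_query_signature([profile(["g1", "g2", "g3"])], top_n=2)


class TestDrugDrugConnectivity:
    def test_self_query_is_maximal(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i:04d}" for i in range(1, 1001)]
        prof = profile(list(rng.permutation(genes)), name="self")
        out = ks.drug_drug_connectivity([prof], [prof], top_n=50)
        n, m = 1000, 50
        # up set occupies [1..m], down set [n-m+1..n]
        expected = (1 - m / n) + (n - m + 1) / n
        assert out["score"] == pytest.approx(expected)
        assert out["normalized"] == pytest.approx(expected / 2)
        assert out["normalization"] == "ts/2"

    def test_reverse_profile_negates_the_score(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i:04d}" for i in range(1, 1001)]
        fwd = list(rng.permutation(genes))
        p_fwd = profile(fwd, name="fwd")
        p_rev = profile(list(reversed(fwd)), name="rev")
        self_score = ks.drug_drug_connectivity([p_fwd], [p_fwd], top_n=50)["score"]
        anti = ks.drug_drug_connectivity([p_fwd], [p_rev], top_n=50)["score"]
        tol = 2 * (1 / 50 - 1 / 1000)  # per-side reversal slack
        assert anti == pytest.approx(-self_score, abs=tol + 1e-12)

    def test_independent_null_drugs_score_near_zero(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i:04d}" for i in range(1, 1001)]
        scores = []
        for _ in range(20):
            a = profile(list(rng.permutation(genes)), name="a")
            b = profile(list(rng.permutation(genes)), name="b")
            scores.append(ks.drug_drug_connectivity([a], [b], top_n=100)["score"])
        assert abs(np.mean(scores)) < 0.1


def test_instance_library_readers_are_bit_equivalent(tmp_path, study_dataset):
    profiles = study_dataset.instances[:4]
    long_path = tmp_path / "long.tsv"
    mat_path = tmp_path / "matrix.tsv"
    write_instances_long(profiles, long_path)
    write_instances_rank_matrix(profiles, mat_path)
    from_long = read_instances_long(long_path)
    from_mat = read_instances_rank_matrix(mat_path)
    key = lambda p: (p.instance_id, p.drug_name)
    for a, b in zip(sorted(from_long, key=key), sorted(from_mat, key=key)):
        assert a.instance_id == b.instance_id
        assert a.drug_name == b.drug_name
        assert a.ranked_genes == b.ranked_genes


def test_duplicate_genes_rejected_at_type_level():
    with pytest.raises(ProfileError):
        profile(["g1", "g1", "g2"])
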