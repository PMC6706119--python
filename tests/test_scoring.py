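"""Specificity (MIT-style) and efficiency scoring."""

import itertools

import pytest

from crisprkit import (
    EfficiencyModel,
    GenomeSequence,
    GenomicInterval,
    MIT_MISMATCH_WEIGHTS,
    MismatchWeightVector,
    OffTargetHit,
    ProtospacerSite,
    aggregate_specificity,
    efficiency_score,
    load_efficiency_model,
    score_guide,
    single_hit_score,
    truncated_weights,
)

SPACER20 = "ACGTACGTACGTACGTACGT"


def make_hit(positions, L=20, pam="TGG"):
    cls = "NGG" if pam[1:] == "GG" else "NAG"
    return OffTargetHit(
        locus=GenomicInterval("c", 0, L, "+"),
        strand="+",
        sequence="A" * L,
        pam=pam,
        pam_class=cls,
        mismatch_count=len(positions),
        mismatch_positions=sorted(positions),
    )


class TestSingleHitScore:
    def test_zero_mismatches_scores_one(self):
        assert single_hit_score(SPACER20, make_hit([])) == 1.0

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (20, 1 - 0.583),  # PAM-proximal position, weight 0.583
            (1, 1.0),  # PAM-distal position, weight 0
            (14, 1 - 0.851),
        ],
    )
    def test_single_mismatch_no_distance_penalty(self, pos, expected):
        assert single_hit_score(SPACER20, make_hit([pos])) == pytest.approx(expected)

    def test_two_mismatch_hand_computation(self):
        # positions 10 and 20: product (1-0.079)(1-0.583); dbar = 10,
        # D = 1/(((19-10)/19)*4+1); n^2 = 4
        expected = (1 - 0.079) * (1 - 0.583) / ((9 / 19) * 4 + 1) / 4
        got = single_hit_score(SPACER20, make_hit([10, 20]))
        assert got == pytest.approx(expected)

    def test_adjacent_mismatches_penalized_harder_than_spread(self):
        # same weights (both zero): positions {1,2} adjacent vs {1,20} spread
        tight = single_hit_score(SPACER20, make_hit([1, 2]))
        spread = single_hit_score(SPACER20, make_hit([1, 8]))
        assert tight < spread

    def test_bounds_over_all_small_position_sets(self):
        """Score stays in [0,1] for every <=3-mismatch position set, L=20."""
        for n in (1, 2, 3):
            for positions in itertools.combinations(range(1, 21), n):
                s = single_hit_score(SPACER20, make_hit(list(positions)))
                assert 0.0 <= s <= 1.0

    def test_zero_weight_position_leaves_product_unchanged(self):
        # adding position 4 (weight 0) to {20} changes only D and n^2 terms
        base = single_hit_score(SPACER20, make_hit([20]))
        more = single_hit_score(SPACER20, make_hit([4, 20]))
        dbar = (20 - 4) / 1
        d_factor = 1 / (((19 - dbar) / 19) * 4 + 1)
        assert more == pytest.approx(base * d_factor / 4)

    def test_position_out_of_range_errors(self):
        with pytest.raises(ValueError, match="out of range"):
            single_hit_score(SPACER20, make_hit([21]))

    def test_weight_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length"):
            single_hit_score(SPACER20, make_hit([3]), truncated_weights())


class TestAggregate:
    def test_no_hits_scores_100(self):
        assert aggregate_specificity([]) == 100.0

    def test_one_perfect_duplicate_scores_50(self):
        assert aggregate_specificity([1.0]) == pytest.approx(50.0)

    def test_two_perfect_duplicates(self):
        assert aggregate_specificity([1.0, 1.0]) == pytest.approx(10000 / 300)

    def test_strictly_decreasing_per_added_hit(self):
        scores: list[float] = []
        last = 100.0
        for s in (0.9, 0.5, 0.01, 0.3):
            scores.append(s)
            cur = aggregate_specificity(scores)
            assert cur < last
            last = cur

    def test_permutation_invariant(self):
        assert aggregate_specificity([0.2, 0.7, 0.05]) == aggregate_specificity(
            [0.7, 0.05, 0.2]
        )

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            aggregate_specificity([1.2])


class TestTruncated:
    def test_default_vector_matches_printed_values(self):
        assert MismatchWeightVector().weights == MIT_MISMATCH_WEIGHTS
        assert len(MIT_MISMATCH_WEIGHTS) == 20

    def test_truncation_drops_first_two(self):
        t = truncated_weights()
        assert len(t) == 18
        assert t.weights == MIT_MISMATCH_WEIGHTS[2:]
        assert t.weights[0] == 0.014 and t.weights[-1] == 0.583

    def test_all_zero_vector(self):
        assert truncated_weights(tuple([0.0] * 20)).weights == tuple([0.0] * 18)

    def test_wrong_length_errors(self):
        with pytest.raises(ValueError):
            truncated_weights(tuple([0.0] * 18))

    def test_truncated_scoring_equals_rescaled_20mer(self):
        """18-mer scoring = 20-mer scoring with the two PAM-distal positions
        deleted and positions shifted by 2, enumerated over small sets."""
        spacer18 = SPACER20[2:]
        t = truncated_weights()
        for positions20 in itertools.combinations(range(3, 21), 2):
            positions18 = [p - 2 for p in positions20]
            h18 = make_hit(list(positions18), L=18)
            manual = 1.0
            for p in positions18:
                manual *= 1 - t.weights[p - 1]
            dbar = (max(positions18) - min(positions18)) / 1
            manual *= 1 / (((17 - dbar) / 17) * 4 + 1) / 4
            assert single_hit_score(spacer18, h18, t) == pytest.approx(manual)


class TestScoreGuide:
    def test_fills_hit_scores_and_applies_pam_multiplier(self):
        hits = [make_hit([20]), make_hit([20], pam="TAG")]
        res = score_guide(SPACER20, hits, pam_multipliers={"NAG": 0.5})
        assert hits[0].hit_score == pytest.approx(0.417)
        assert hits[1].hit_score == pytest.approx(0.417 * 0.5)
        assert res.aggregate == pytest.approx(
            10000 / (100 + 100 * (0.417 + 0.2085))
        )


EFF_TSV = """#model toy
#window 1 20 3 2
#intercept 0.1
1\tA\t0.2
2\tC\t-0.05
26\tG\t0.3
"""


class TestEfficiency:
    @pytest.fixture
    def model(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(EFF_TSV)
        return load_efficiency_model(p)

    def test_loaded_geometry_and_coefficients(self, model):
        assert model.window_offsets == (1, 20, 3, 2)
        assert model.intercept == pytest.approx(0.1)
        assert model.coefficients[(1, "A")] == pytest.approx(0.2)

    def test_score_context_hand_sum(self, model):
        context = "A" + "C" + "G" * 19 + "TGG" + "AG"
        # pos1 A: +0.2; pos2 C: -0.05; pos26 is the final "G"? window len 26
        assert len(context) == model.window_length
        expected = 0.1 + 0.2 - 0.05 + (0.3 if context[25] == "G" else 0)
        assert model.score_context(context) == pytest.approx(expected)

    def test_intercept_only_model(self, tmp_path):
        p = tmp_path / "i.tsv"
        p.write_text("#window 1 20 3 2\n#intercept 0.7\n")
        m = load_efficiency_model(p)
        assert m.score_context("A" * 26) == pytest.approx(0.7)

    def test_position_beyond_window_errors(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("#window 1 20 3 2\n#intercept 0\n27\tA\t0.5\n")
        with pytest.raises(ValueError, match="outside window"):
            load_efficiency_model(p)

    def test_missing_header_errors(self, tmp_path):
        p = tmp_path / "noh.tsv"
        p.write_text("1\tA\t0.5\n")
        with pytest.raises(ValueError, match="header"):
            load_efficiency_model(p)

    def test_strand_symmetry_and_edge_handling(self, model):
        from crisprkit import reverse_complement

        core = "A" + SPACER20 + "TGGAG"
        # plus-strand site at 10; minus-strand context equal by construction
        genome = GenomeSequence(
            {"c": "T" * 9 + core + "T" * 5 + reverse_complement(core) + "T" * 9}
        )
        plus = ProtospacerSite(
            GenomicInterval("c", 10, 30, "+"), "+", SPACER20, "TGG", 20
        )
        minus_start = 9 + len(core) + 5 + 5  # spacer start inside the RC block
        minus = ProtospacerSite(
            GenomicInterval("c", minus_start, minus_start + 20, "-"),
            "-",
            SPACER20,
            "TGG",
            20,
        )
        s_plus = efficiency_score(plus, genome, model)
        s_minus = efficiency_score(minus, genome, model)
        assert s_plus is not None and s_plus == pytest.approx(s_minus)
        # a site whose window would run off the contig scores as missing
        edge = ProtospacerSite(
            GenomicInterval("c", 0, 20, "+"), "+", "T" * 9 + "A" + SPACER20[:10], "TGG", 20
        )
        assert efficiency_score(edge, genome, model) is None

    def test_linearity_in_coefficients(self, tmp_path, model):
        p = tmp_path / "b.tsv"
        p.write_text("#window 1 20 3 2\n#intercept 0.4\n1\tA\t1.0\n5\tT\t-0.2\n")
        other = load_efficiency_model(p)
        combined = EfficiencyModel(
            model.window_offsets,
            {
                k: model.coefficients.get(k, 0) + other.coefficients.get(k, 0)
                for k in set(model.coefficients) | set(other.coefficients)
            },
            model.intercept + other.intercept,
        )
        ctx = "ACGTA" * 5 + "G"
        assert combined.score_context(ctx) == pytest.approx(
            model.score_context(ctx) + other.score_context(ctx)
        )
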