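import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from snapmech.defence_assay import (
    DefenceCounts,
    aggregate_trials,
    attack_rate,
    bonferroni,
    compact_letter_display,
    fisher_exact_two_sided,
    hit_kill_probabilities,
    immobilised_rate,
    pairwise_fisher,
    read_defence_csv,
    two_sided_p_values,
)
from snapmech.errors import SchemaError, UndefinedRateError

from oracles import exhaustive_fisher_p, exhaustive_fisher_ps


class TestRates:
    def test_attack_rates_printed_counts(self):
        cases = [(8, 93, 8.6), (102, 300, 34.0), (33, 143, 23.1), (0, 10, 0.0)]
        for attacks, enc, pct in cases:
            c = DefenceCounts("sp", encounters=enc, attacks=attacks, snaps=0, hits=0, kills=0)
            assert round(100 * attack_rate(c), 1) == pct

    def test_attack_rate_zero_encounters(self):
        c = DefenceCounts("sp", encounters=0, attacks=0, snaps=0, hits=0, kills=0)
        with pytest.raises(UndefinedRateError):
            attack_rate(c)

    def test_hit_probability(self):
        c = DefenceCounts("sp", 20, 5, snaps=12, hits=10, kills=0)
        hit_p, kill_p = hit_kill_probabilities(c)
        assert round(100 * hit_p, 1) == 83.3
        assert kill_p == 0.0

    def test_zero_kills(self):
        c = DefenceCounts("sp", 20, 5, snaps=10, hits=7, kills=0)
        assert hit_kill_probabilities(c)[1] == 0.0

    def test_undefined_flags(self):
        c = DefenceCounts("sp", 20, 5, snaps=0, hits=0, kills=0)
        assert hit_kill_probabilities(c) == (None, None)

    def test_immobilised(self):
        c = DefenceCounts("sp", 20, 5, 10, 5, 0, immobilised=2, ants=24)
        assert round(100 * immobilised_rate(c), 1) == 8.3

    def test_count_invariants(self):
        with pytest.raises(ValueError):
            DefenceCounts("sp", encounters=5, attacks=6, snaps=0, hits=0, kills=0)
        with pytest.raises(ValueError):
            DefenceCounts("sp", 10, 5, snaps=3, hits=4, kills=0)
        with pytest.raises(ValueError):
            DefenceCounts("sp", 10, 5, snaps=5, hits=2, kills=3)


class TestFisher:
    def test_identical_tables(self):
        assert fisher_exact_two_sided([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_perfect_separation(self):
        # only 2 of the C(20,10) equi-margin tables are as extreme
        assert fisher_exact_two_sided([[10, 0], [0, 10]]) == pytest.approx(
            2.0 / 184756.0, rel=1e-9
        )

    def test_degenerate_margins(self):
        assert fisher_exact_two_sided([[0, 0], [3, 4]]) == 1.0
        assert fisher_exact_two_sided([[0, 3], [0, 4]]) == 1.0

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided([[1.5, 2], [3, 4]])

    @given(
        a=st.integers(0, 15), b=st.integers(0, 15),
        c=st.integers(0, 15), d=st.integers(0, 15),
    )
    @settings(max_examples=200)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        assert fisher_exact_two_sided([[a, b], [c, d]]) == pytest.approx(
            exhaustive_fisher_p(a, b, c, d), abs=1e-10
        )

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(max_examples=100)
    def test_matches_scipy(self, a, b, c, d):
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            return
        assert fisher_exact_two_sided([[a, b], [c, d]]) == pytest.approx(
            scipy_fisher([[a, b], [c, d]])[1], rel=1e-7
        )

    def test_vectorized_matches_oracle_small_sweep(self):
        for r1 in range(1, 13):
            for r2 in range(1, 13):
                for c1 in range(1, r1 + r2):
                    impl = two_sided_p_values(r1, r2, c1)
                    orc = exhaustive_fisher_ps(r1, r2, c1)
                    np.testing.assert_allclose(impl, orc, atol=1e-12)


class TestBonferroni:
    def test_definition(self):
        assert bonferroni(0.01, 6) == pytest.approx(0.06)
        assert bonferroni(0.3, 6) == 1.0

    @given(p=st.floats(0.0, 1.0), m=st.integers(1, 20))
    def test_adjusted_dominates_raw(self, p, m):
        adj = bonferroni(p, m)
        assert adj >= p
        assert 0.0 <= adj <= 1.0


@pytest.fixture
def four_species():
    return [
        DefenceCounts("gA", 93, 8, snaps=98, hits=81, kills=74),
        DefenceCounts("gB", 107, 18, snaps=100, hits=14, kills=13),
        DefenceCounts("sA", 300, 102, snaps=108, hits=31, kills=0, immobilised=2, ants=24),
        DefenceCounts("sB", 143, 33, snaps=68, hits=27, kills=0),
    ]


class TestPairwise:
    def test_six_pairs_adjusted(self, four_species):
        pairs = pairwise_fisher(four_species, "hit")
        assert len(pairs) == 6
        for r in pairs.itertuples(index=False):
            assert r.p_adj == pytest.approx(min(1.0, 6 * r.p_raw))

    def test_zero_denominator_skipped(self):
        counts = [
            DefenceCounts("x", 10, 5, snaps=0, hits=0, kills=0),
            DefenceCounts("y", 10, 5, snaps=10, hits=5, kills=0),
        ]
        pairs = pairwise_fisher(counts, "hit")
        assert pairs["skipped"].all()
        assert pairs["p_raw"].isna().all()

    def test_invalid_outcome(self, four_species):
        with pytest.raises(ValueError):
            pairwise_fisher(four_species, "bite")

    def test_letters_cover_nonsignificant_pairs(self, four_species):
        pairs = pairwise_fisher(four_species, "hit")
        letters = compact_letter_display(four_species, pairs, "hit")
        for r in pairs.itertuples(index=False):
            shared = set(letters[r.species_a]) & set(letters[r.species_b])
            if r.p_adj < 0.05:
                assert not shared, (r.species_a, r.species_b)
            else:
                assert shared, (r.species_a, r.species_b)

    def test_identical_species_share_letter(self):
        same = [DefenceCounts(s, 10, 5, snaps=10, hits=5, kills=5) for s in "wxyz"]
        pairs = pairwise_fisher(same, "hit")
        letters = compact_letter_display(same, pairs, "hit")
        assert set(letters.values()) == {"a"}


class TestAggregation:
    def test_pooling_equivariance(self):
        # rates computed on pooled counts equal rates on the summed trials
        trials = pd.DataFrame({
            "species": ["sp"] * 3,
            "trial_id": [1, 2, 3],
            "encounters": [10, 20, 30],
            "attacks": [1, 4, 9],
            "snaps": [5, 10, 15],
            "hits": [2, 3, 5],
            "kills": [1, 1, 2],
        })
        (c,) = aggregate_trials(trials)
        assert attack_rate(c) == pytest.approx(14 / 60)
        hit_p, kill_p = hit_kill_probabilities(c)
        assert hit_p == pytest.approx(10 / 30)
        assert kill_p == pytest.approx(4 / 10)

    def test_read_csv_missing_column(self, tmp_path):
        p = tmp_path / "defence.csv"
        p.write_text("species,trial_id,encounters,attacks,snaps,hits\nx,1,1,0,0,0\n")
        with pytest.raises(SchemaError, match="kills"):
            read_defence_csv(p)

    def test_optional_columns_aggregate(self, tmp_path):
        p = tmp_path / "defence.csv"
        p.write_text(
            "species,trial_id,encounters,attacks,snaps,hits,kills,immobilised,ants\n"
            "x,1,10,2,5,3,1,1,4\nx,2,10,2,5,3,1,1,4\n"
        )
        (c,) = aggregate_trials(read_defence_csv(p))
        assert c.immobilised == 2
        assert c.ants == 8
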