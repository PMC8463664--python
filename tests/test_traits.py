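"""Trait coding rules: thresholds, binarizations, transforms, residuals."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylocare import (
    alkaloid_presence,
    binarize_conspicuous,
    code_trait_table,
    conspicuousness_score,
    log_transform,
    median_of_range,
    sexual_size_dimorphism,
    size_controlled_residuals,
)
from phylocare.simulate import simulate_brownian, simulate_yule_tree
from phylocare.traits import (
    code_caregiver,
    code_deposition,
    code_transporter,
    parse_numeric_or_range,
    read_trait_table,
)


class TestConspicuousness:
    @pytest.mark.parametrize(
        "segments,expected",
        [
            ([1] * 11, 11),
            ([0] * 11, 0),
            ([1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0], 6),
        ],
    )
    def test_score_is_segment_sum(self, segments, expected):
        assert conspicuousness_score(segments) == expected

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError, match="11"):
            conspicuousness_score([1] * 10)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            conspicuousness_score([2] + [0] * 10)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 1), min_size=11, max_size=11))
    def test_score_threshold_consistency(self, segments):
        score = conspicuousness_score(segments)
        assert 0 <= score <= 11
        assert binarize_conspicuous(score) == (1 if score >= 6 else 0)

    @pytest.mark.parametrize("score,expected", [(6, 1), (5, 0), (11, 1), (0, 0)])
    def test_conspicuous_threshold(self, score, expected):
        assert binarize_conspicuous(score) == expected

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError):
            binarize_conspicuous(12)


class TestAlkaloids:
    @pytest.mark.parametrize("level,expected", [(0, 0), (10.0, 0), (50, 1), (10.01, 1)])
    def test_presence_threshold_strict(self, level, expected):
        assert alkaloid_presence(level) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            alkaloid_presence(-1)


class TestSizeTraits:
    @pytest.mark.parametrize(
        "f,m,expected",
        [(27.46, 24.55, 1.1185), (20, 20, 1.0), (16, 14, 1.1429)],
    )
    def test_ssd_ratio(self, f, m, expected):
        assert sexual_size_dimorphism(f, m) == pytest.approx(expected, abs=1e-4)

    def test_ssd_missing_propagates(self):
        assert np.isnan(sexual_size_dimorphism(float("nan"), 20))

    @pytest.mark.parametrize("lo,hi,expected", [(1, 40, 20.5), (12, 12, 12), (2, 5, 3.5)])
    def test_median_of_range(self, lo, hi, expected):
        assert median_of_range(lo, hi) == pytest.approx(expected)

    def test_reversed_range_rejected(self):
        with pytest.raises(ValueError):
            median_of_range(5, 2)

    def test_range_string_parsing(self):
        assert parse_numeric_or_range("1-40") == pytest.approx(20.5)
        assert parse_numeric_or_range("12") == 12
        assert np.isnan(parse_numeric_or_range("NA"))

    def test_log_transform(self):
        out = log_transform(np.array([1.0, np.e, np.nan]))
        assert out[0] == pytest.approx(0.0)
        assert out[1] == pytest.approx(1.0)
        assert np.isnan(out[2])

    def test_log_transform_rejects_nonpositive_by_name(self):
        s = pd.Series([1.0, 0.0], index=["good_sp", "bad_sp"])
        with pytest.raises(ValueError, match="bad_sp"):
            log_transform(s)


class TestDiscreteCoding:
    def test_caregiver_rules(self):
        assert code_caregiver("male")[0] == "male"
        assert code_caregiver("female")[0] == "female"
        code, reason = code_caregiver("none")
        assert code == "excluded" and reason == "no_parental_care"
        code, reason = code_caregiver("both")
        assert code == "excluded" and "ambiguous" in reason
        assert np.isnan(code_caregiver("NA")[0])

    def test_transporter_majority_and_tie(self):
        assert code_transporter("both", 5, 1)[0] == "male"
        assert code_transporter("female")[0] == "female"
        code, reason = code_transporter("both", 3, 3)
        assert np.isnan(code) and reason == "transporter_sex_tie"

    def test_deposition_binarization(self):
        assert code_deposition("pond") == 0
        assert code_deposition("multiple") == 0
        assert code_deposition("phytotelm") == 1
        assert np.isnan(code_deposition("NA"))


RAW_CSV = """species,caregiver,transporter,transporter_obs_male,transporter_obs_female,habitat,deposition,cannibalism,male_svl,female_svl,clutch_size,egg_size,tadpole_size,n_tadpoles_carried,conspicuousness_score,alkaloid_ug_per_100mg
Sp one,male,male,NA,NA,far_stream,stream,absent,24.55,27.46,1-40,2.1,12.5,8,7,55
Sp_two,none,both,3,3,near_stream,phytotelm,present,14,16,3,1.5,10.2,1,4,2
Sp_three,both,both,5,1,far_stream,multiple,NA,20,20,12,NA,NA,2,6,10
Sp_four,NA,female,NA,NA,near_stream,pond,NA,18,21,NA,1.9,14.0,NA,2,NA
"""


class TestTableCoding:
    def test_coding_and_exclusions(self):
        raw = read_trait_table(io.StringIO(RAW_CSV))
        res = code_trait_table(raw)
        coded = res.coded
        assert coded.loc["Sp_one", "conspicuous"] == 1
        assert coded.loc["Sp_two", "conspicuous"] == 0
        assert coded.loc["Sp_three", "conspicuous"] == 1  # score 6 is conspicuous
        assert coded.loc["Sp_one", "alkaloids_present"] == 1
        assert coded.loc["Sp_three", "alkaloids_present"] == 0  # exactly 10 -> absent
        assert coded.loc["Sp_one", "log_clutch_size"] == pytest.approx(np.log(20.5))
        assert coded.loc["Sp_one", "ssd"] == pytest.approx(27.46 / 24.55)
        # exclusions carry machine-readable reasons
        excl = res.exclusions.set_index(["species", "field"])["reason"]
        assert excl[("Sp_two", "caregiver")] == "no_parental_care"
        assert excl[("Sp_three", "caregiver")] == "ambiguous_biparental_care"
        assert excl[("Sp_two", "transporter")] == "transporter_sex_tie"
        # majority transporter assignment
        assert coded.loc["Sp_three", "transporter_female"] == 0.0
        assert coded.loc["Sp_four", "transporter_female"] == 1.0

    def test_coding_is_deterministic(self):
        raw = read_trait_table(io.StringIO(RAW_CSV))
        a = code_trait_table(raw).coded.to_csv()
        b = code_trait_table(raw).coded.to_csv()
        assert a == b

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            code_trait_table(pd.DataFrame())


class TestResiduals:
    def test_proportional_trait_gives_zero_residuals(self, yule100):
        size = simulate_brownian(yule100, 1.0, 3.0, seed=1)
        trait = 2.0 * size + 1.0
        r = size_controlled_residuals(trait, size, yule100)
        assert np.max(np.abs(r)) < 1e-8

    def test_star_tree_residuals_equal_ols(self):
        from phylocare import parse_newick

        star = parse_newick("(A:1,B:1,C:1,D:1,E:1,F:1);")
        rng = np.random.default_rng(3)
        size = rng.normal(10, 1, 6)
        trait = rng.normal(0, 1, 6)
        r = size_controlled_residuals(trait, size, star)
        X = np.column_stack([np.ones(6), size])
        beta = np.linalg.lstsq(X, trait, rcond=None)[0]
        assert np.allclose(r, trait - X @ beta, atol=1e-8)

    def test_allometric_slope_recovery(self, yule100):
        # simulated allometry: trait = 0.75 * size + Brownian noise
        from phylocare.regression import pgls

        size = simulate_brownian(yule100, 1.0, 0.0, seed=10)
        noise = simulate_brownian(yule100, 0.25, 0.0, seed=11)
        trait = 0.75 * size + noise
        fit = pgls(trait, size, yule100)
        assert abs(fit.slope - 0.75) < 3 * fit.slope_se

    def test_too_few_pairs_rejected(self, yule100):
        vals = np.full(100, np.nan)
        vals[:2] = 1.0
        with pytest.raises(ValueError, match="3"):
            size_controlled_residuals(vals, vals, yule100)

    def test_missing_propagates(self, yule100):
        size = simulate_brownian(yule100, 1.0, 3.0, seed=2)
        trait = 2 * size.copy()
        trait[5] = np.nan
        r = size_controlled_residuals(trait, size, yule100)
        assert np.isnan(r[5]) and not np.isnan(r[6])
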