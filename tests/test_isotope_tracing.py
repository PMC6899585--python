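import numpy as np
import pytest

from cadtrace.feature_core import FeatureID, FeatureMatrix, SampleMeta
from cadtrace.isotope_tracing import (ClassificationThresholds, EnrichmentRecord,
                                      IsotopologPair, PairSearchParams,
                                      TracingError, classify_all,
                                      classify_labeling, compute_ef, correct_ef,
                                      enrichment_records, find_isotopolog_pairs,
                                      find_reference_pair)
from cadtrace.synthetic_data import (DELTA_15N, default_panel,
                                     natural_heavy_fraction, protonated_mz,
                                     simulate_feature_tables, tracing_scenario)


def brute_force_pairs(matrix, params):
    """Independent O(n^2) all-pairs oracle for the pair search."""
    pairs = []
    for light in matrix.features:
        expected = light.mz + params.delta_mass
        best = None
        for cand in matrix.features:
            if cand == light or cand.mode != light.mode:
                continue
            ppm = abs(cand.mz - expected) / expected * 1e6
            drt = abs(cand.rt - light.rt)
            if ppm >= params.ppm_tolerance or drt > params.rt_tolerance:
                continue
            key = (ppm, drt, cand.mz)
            if best is None or key < best[0]:
                best = (key, cand)
        if best is not None:
            pairs.append((light.render(), best[1].render()))
    return sorted(pairs)


def _matrix_from_features(features):
    samples = [SampleMeta("s1", "DC29", "AL", 1), SampleMeta("s2", "DC29", "AL", 2)]
    values = np.full((len(features), 2), 10000.0)
    return FeatureMatrix(features, samples, values)


def random_feature_table(rng, n=50):
    features = set()
    while len(features) < n:
        mode = "RP" if rng.random() < 0.5 else "HI"
        base = FeatureID.make(mode, float(rng.uniform(0.5, 30)),
                              float(rng.uniform(60, 700)))
        features.add(base)
        if rng.random() < 0.4 and len(features) < n:   # plant a plausible partner
            features.add(FeatureID.make(
                mode, base.rt + float(rng.normal(0, 0.05)),
                base.mz + DELTA_15N + float(rng.normal(0, 3e-4))))
    return _matrix_from_features(sorted(features))


class TestPairSearch:
    def test_printed_cadaverine_pair_detected(self):
        m = _matrix_from_features([FeatureID.parse("RP_1.63/103.1233"),
                                   FeatureID.parse("RP_1.63/104.1203")])
        pairs = find_isotopolog_pairs(m)
        assert len(pairs) == 1
        assert pairs[0].observed_shift == pytest.approx(0.997, abs=5e-4)
        assert abs(pairs[0].ppm_error) < 5

    def test_rt_difference_beyond_tolerance_rejected(self):
        m = _matrix_from_features([FeatureID.parse("RP_1.63/103.1233"),
                                   FeatureID.parse("RP_1.88/104.1203")])
        assert find_isotopolog_pairs(m) == []

    def test_modes_never_mix(self):
        m = _matrix_from_features([FeatureID.parse("RP_1.63/103.1233"),
                                   FeatureID.parse("HI_1.63/104.1203")])
        assert find_isotopolog_pairs(m) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_feature_table(rng)
        params = PairSearchParams()
        ours = sorted((p.light.render(), p.heavy.render())
                      for p in find_isotopolog_pairs(m, params))
        assert ours == brute_force_pairs(m, params)

    def test_invalid_pair_orientation_rejected(self):
        with pytest.raises(TracingError):
            IsotopologPair(FeatureID.parse("RP_1.63/104.1203"),
                           FeatureID.parse("RP_1.63/103.1233"), -0.997, 0.0, 0.0)


class TestEf:
    def test_equal_intensities_give_fifty_percent(self):
        assert compute_ef(1234.0, 1234.0) == 50.0

    def test_natural_abundance_regime(self):
        assert compute_ef(9930.0, 70.0) == pytest.approx(0.70)

    def test_zero_heavy_gives_zero(self):
        assert compute_ef(5000.0, 0.0) == 0.0

    def test_both_zero_flagged(self):
        with pytest.raises(TracingError, match="undefined"):
            compute_ef(0.0, 0.0)

    def test_strictly_increasing_in_heavy_intensity(self):
        efs = [compute_ef(1000.0, h) for h in (0.0, 10.0, 100.0, 1000.0, 1e6)]
        assert all(b > a for a, b in zip(efs, efs[1:]))
        assert all(0 <= e <= 100 for e in efs)


class TestCorrection:
    def test_normalization_formula(self):
        corrected, below = correct_ef(50.35, 0.7)
        assert corrected == pytest.approx(100 * (50.35 - 0.7) / (100 - 0.7))
        assert corrected == pytest.approx(50.0, abs=0.01)
        assert not below

    def test_treated_equal_baseline_gives_zero(self):
        assert correct_ef(0.7, 0.7)[0] == 0.0

    def test_zero_baseline_identity(self):
        assert correct_ef(42.0, 0.0) == (42.0, False)

    def test_below_baseline_floored_and_flagged(self):
        corrected, below = correct_ef(0.3, 0.7)
        assert corrected == 0.0 and below

    def test_subtraction_variant(self):
        assert correct_ef(50.35, 0.7, method="subtract")[0] == pytest.approx(49.65)


def _record(ef_al=None, ef_el=None):
    pair = IsotopologPair(FeatureID.parse("RP_2.34/102.0917"),
                          FeatureID.parse("RP_2.34/103.0887"), 0.997, 0.0, 0.0)
    out = {}
    for treatment, ef in (("AL", ef_al), ("EL", ef_el)):
        if ef is not None:
            out[treatment] = EnrichmentRecord(pair, treatment, 1e5, 1e4, [ef],
                                              ef, corrected_ef=ef)
    return out.get("AL"), out.get("EL")


def _reference(ef_al=66.7, ef_el=56.2):
    pair = IsotopologPair(FeatureID.parse("RP_1.63/103.1233"),
                          FeatureID.parse("RP_1.63/104.1203"), 0.997, 0.0, 0.0)
    return (EnrichmentRecord(pair, "AL", 1e5, 1e4, [ef_al], ef_al, corrected_ef=ef_al),
            EnrichmentRecord(pair, "EL", 1e5, 1e4, [ef_el], ef_el, corrected_ef=ef_el))


class TestClassification:
    def test_cadaverine_level_labeling_is_both_nitrogens(self):
        # 54.7-64.1% vs the 66.7/56.2% reference: rho ~ 0.97
        al, el = _record(64.1, 54.7)
        out = classify_labeling(al, el, *_reference())
        assert out.label_class == "both_nitrogens"
        assert out.rho == pytest.approx(0.97, abs=0.02)

    def test_half_level_labeling_is_one_nitrogen_symmetric(self):
        al, el = _record(34.1, 25.9)
        out = classify_labeling(al, el, *_reference())
        assert out.label_class == "one_nitrogen_via_symmetric_intermediate"
        assert out.rho == pytest.approx(0.49, abs=0.02)

    def test_al_only_labeling_is_regiospecific_alpha(self):
        al, el = _record(88.0, 1.0)
        out = classify_labeling(al, el, *_reference())
        assert out.label_class == "regiospecific_alpha"

    def test_el_only_labeling_is_regiospecific_epsilon(self):
        al, el = _record(2.0, 70.0)
        out = classify_labeling(al, el, *_reference())
        assert out.label_class == "regiospecific_epsilon"

    def test_below_threshold_everywhere_is_unlabeled(self):
        al, el = _record(1.0, 2.0)
        out = classify_labeling(al, el, *_reference())
        assert out.label_class == "unlabeled"

    def test_intermediate_ratio_is_ambiguous(self):
        al, el = _record(45.0, 40.0)       # rho ~ 0.69: between the bands
        out = classify_labeling(al, el, *_reference())
        assert out.label_class == "ambiguous"

    def test_strong_asymmetry_is_ambiguous(self):
        al, el = _record(60.0, 20.0)       # asymmetry 1.0 > 0.5
        out = classify_labeling(al, el, *_reference())
        assert out.label_class == "ambiguous"

    def test_missing_treatment_is_ambiguous_with_reason(self):
        al, _ = _record(60.0, None)
        out = classify_labeling(al, None, *_reference())
        assert out.label_class == "ambiguous" and "missing" in out.reason

    def test_unenriched_reference_rejected(self):
        al, el = _record(30.0, 30.0)
        ref_al, ref_el = _reference(2.0, 1.0)
        with pytest.raises(TracingError, match="reference"):
            classify_labeling(al, el, ref_al, ref_el)


class TestEndToEnd:
    def test_nl_feeding_reproduces_natural_abundance(self, tracing_run):
        scenario, matrices, truth = tracing_run
        tol_factor = 3 * scenario.noise_cv / np.sqrt(scenario.replicates_per_group)
        for mode, matrix in matrices.items():
            pairs = find_isotopolog_pairs(matrix)
            records = enrichment_records(matrix, pairs)
            truth_n = truth.set_index("feature_id").n_nitrogen
            for rec in records:
                if rec.treatment != "NL" or np.isnan(rec.raw_ef):
                    continue
                if not rec.replicate_efs or min(rec.replicate_efs) == 0:
                    continue  # M+1 censored below the detection cut-off
                n_n = int(truth_n[rec.pair.light.render()])
                expected = natural_heavy_fraction(n_n) * 100
                assert rec.raw_ef == pytest.approx(
                    expected, abs=max(tol_factor * expected, 1e-9))

    def test_generator_compounds_classified_correctly(self, tracing_run):
        _, matrices, truth = tracing_run
        truth_by_feature = truth.set_index("feature_id")
        expected_map = {
            "one_nitrogen_from_cadaverine": "one_nitrogen_via_symmetric_intermediate",
            "both_nitrogens_from_cadaverine": "both_nitrogens",
            "alpha_nitrogen_only": "regiospecific_alpha",
            "unlabeled_background": "unlabeled",
        }
        for mode, matrix in matrices.items():
            pairs = find_isotopolog_pairs(matrix)
            records = enrichment_records(matrix, pairs)
            reference = find_reference_pair(pairs, protonated_mz("C5H14N2"))
            assert truth_by_feature.loc[
                reference.light.render(), "compound_id"] == "cadaverine"
            for cls in classify_all(records, reference.light):
                label = truth_by_feature.loc[cls.feature.render(), "label_class"]
                assert cls.label_class == expected_map[label], cls

    def test_reference_lookup_fails_cleanly_without_pairs(self):
        with pytest.raises(TracingError):
            find_reference_pair([], 103.123)
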