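"""PSPI, zone-max and emotion-weighted pain scores, and level binning."""

import numpy as np
import pytest

import painface as pf
from painface.au_zones import ZoneIntensities
from painface.errors import InvalidArgumentError, SchemaError
from painface.pain_score import PSPIConfig


class TestPSPI:
    def test_all_zero(self):
        assert pf.pspi_ple(0, 0, 0, 0, 0, 0) == 0.0

    def test_maximum_is_clamped_to_15(self):
        assert pf.pspi_ple(5, 5, 3, 4, 5, 1) == 15.0

    def test_hand_sum(self):
        # 2 + max(1,3) + max(0,2) + 1 = 8
        assert pf.pspi_ple(2, 1, 3, 0, 2, 1) == 8.0

    def test_unclamped_raw_sum_reaches_16(self):
        cfg = PSPIConfig(clamp_to_paper_range=False)
        assert pf.pspi_ple(5, 5, 5, 5, 5, 1, cfg) == 16.0

    def test_clamped_range(self, rng):
        for _ in range(50):
            a4, a6, a7, a9, a10 = rng.uniform(0, 5, 5)
            a43 = float(rng.integers(0, 2))
            s = pf.pspi_ple(a4, a6, a7, a9, a10, a43)
            assert 0 <= s <= 15

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pf.pspi_ple(6, 0, 0, 0, 0, 0)
        with pytest.raises(InvalidArgumentError):
            pf.pspi_ple(0, 0, 0, 0, 0, 0.5)


class TestZoneMax:
    def _zi(self, **kw):
        vals = {au: [0.0] for au in ("AU1", "AU6", "AU9", "AU15", "AU17", "AU44")}
        vals.update(kw)
        return ZoneIntensities(vals)

    def test_all_zero(self):
        assert pf.zone_max_ple(self._zi()) == 0.0

    def test_unit_maxima_sum_to_six(self):
        zi = self._zi(**{au: [1.0, 0.2] for au in ("AU1", "AU6", "AU9", "AU15", "AU17", "AU44")})
        assert pf.zone_max_ple(zi) == pytest.approx(6.0)

    def test_matches_bruteforce_scan(self, rng):
        vals = {au: list(rng.uniform(0, 5, rng.integers(1, 8))) for au in
                ("AU1", "AU6", "AU9", "AU15", "AU17", "AU44")}
        zi = ZoneIntensities(vals)
        brute = sum(max(v) for v in vals.values())  # exhaustive per-zone scan
        assert pf.zone_max_ple(zi) == pytest.approx(brute, abs=1e-12)

    def test_missing_zone_is_schema_error(self):
        zi = ZoneIntensities({"AU1": [1.0]})
        with pytest.raises(SchemaError):
            pf.zone_max_ple(zi)

    def test_permutation_invariant_and_monotone(self, rng):
        vals = {au: rng.uniform(0, 4, 5) for au in
                ("AU1", "AU6", "AU9", "AU15", "AU17", "AU44")}
        base = pf.zone_max_ple(ZoneIntensities(vals))
        shuffled = {au: rng.permutation(v) for au, v in vals.items()}
        assert pf.zone_max_ple(ZoneIntensities(shuffled)) == pytest.approx(base)
        bumped = {au: v.copy() for au, v in vals.items()}
        bumped["AU9"][2] = min(5.0, bumped["AU9"][2] + 1.0)
        assert pf.zone_max_ple(ZoneIntensities(bumped)) >= base


class TestWeightedPle:
    def test_sadness_factor(self, weight_table):
        assert pf.weighted_ple(10.0, "sadness", weight_table) == pytest.approx(17.0)

    def test_neutrality_identity(self, weight_table, rng):
        for ps in rng.uniform(0, 30, 10):
            assert pf.weighted_ple(ps, "neutrality", weight_table) == ps

    def test_soft_uniform_distribution(self, weight_table):
        dist = pf.EmotionDistribution({e: 1 / 7 for e in pf.EMOTIONS})
        # 7 * mean(0.8, 0.9, 1.0, 1.2, 1.4, 1.6, 1.7) = 8.6
        assert pf.weighted_ple(7.0, dist, weight_table, mode="soft") == pytest.approx(8.6)

    def test_hard_ordering_follows_weight_table(self, weight_table):
        ps = 5.0
        outs = [pf.weighted_ple(ps, e, weight_table) for e in
                ("happiness", "surprise", "neutrality", "disgust", "fear", "anger", "sadness")]
        assert outs == sorted(outs)

    def test_soft_bounds(self, weight_table, rng):
        ps = 9.0
        w = np.array([pf.DEFAULT_EMOTION_WEIGHTS[e] for e in pf.EMOTIONS])
        for _ in range(20):
            raw = rng.dirichlet(np.ones(7))
            dist = pf.EmotionDistribution(dict(zip(pf.EMOTIONS, raw)))
            out = pf.weighted_ple(ps, dist, weight_table, mode="soft")
            assert w.min() * ps - 1e-9 <= out <= w.max() * ps + 1e-9
        one_hot = pf.EmotionDistribution(
            {e: (1.0 if e == "sadness" else 0.0) for e in pf.EMOTIONS}
        )
        assert pf.weighted_ple(ps, one_hot, weight_table, mode="soft") == pytest.approx(
            1.7 * ps
        )

    def test_unknown_label_mirrors_none_guard(self, weight_table):
        with pytest.raises(InvalidArgumentError):
            pf.weighted_ple(1.0, "confusion", weight_table)


class TestBinPainLevel:
    @pytest.mark.parametrize(
        "score, level",
        [(0.0, 0), (0.001, 1), (6.0, 1), (6.001, 2), (12.0, 2), (18.5, 4),
         (24.0, 4), (30.0, 5), (51.0, 5)],
    )
    def test_default_bins(self, score, level):
        assert pf.bin_pain_level(score) == level

    def test_level_names(self):
        assert pf.PAIN_LEVEL_NAMES[0] == "no pain"
        assert pf.PAIN_LEVEL_NAMES[5] == "worst pain"
        assert len(pf.PAIN_LEVEL_NAMES) == 6

    def test_invalid_inputs(self):
        with pytest.raises(InvalidArgumentError):
            pf.bin_pain_level(-1.0)
        with pytest.raises(InvalidArgumentError):
            pf.bin_pain_level(3.0, thresholds=(6, 5, 18, 24, 30))


class TestComputePain:
    def test_neutral_pair_is_painless(self, template, zone_cfg, cal, weight_matrix, weight_table):
        s = pf.compute_pain(
            template.landmarks, template.landmarks, zone_cfg, cal, weight_matrix, weight_table
        )
        assert s.ps == 0.0 and s.plew == 0.0 and s.level == 0
        assert s.emotion == "neutrality"
        assert s.pspi == 0.0

    def test_sadness_prototype_applies_1p7(self, template, zone_cfg, cal, weight_matrix, weight_table):
        active = pf.apply_activation(
            template, {au: 4.0 for au in pf.EMOTION_PROTOTYPES["sadness"]}, cal
        )
        s = pf.compute_pain(
            template.landmarks, active, zone_cfg, cal, weight_matrix, weight_table
        )
        assert s.emotion == "sadness"
        assert s.plew == pytest.approx(1.7 * s.ps, abs=1e-9)

    def test_staged_oracle_trace(self, template, zone_cfg, cal, weight_matrix, weight_table):
        # replay the pipeline stage by stage and compare every field
        spec = {"AU1": 2.0, "AU9": 3.5, "AU43": 4.0}
        active = pf.apply_activation(template, spec, cal)
        s = pf.compute_pain(
            template.landmarks, active, zone_cfg, cal, weight_matrix, weight_table
        )
        zi = pf.compute_zone_intensities(template.landmarks, active, zone_cfg, cal)
        vec = pf.reduce_to_vector(zi)
        ps = pf.zone_max_ple(zi)
        label, dist = pf.classify_au_vector(vec, weight_matrix)
        plew = pf.weighted_ple(ps, label, weight_table)
        assert s.ps == pytest.approx(ps)
        assert s.emotion == label
        assert s.plew == pytest.approx(plew)
        assert s.level == pf.bin_pain_level(plew)
        assert s.pspi == pytest.approx(
            pf.pspi_ple(vec.get("AU4"), vec.get("AU6"), vec.get("AU7"),
                        vec.get("AU9"), vec.get("AU10"), vec.get("AU43"))
        )

    def test_recovers_analytic_ps_noiselessly(self, template, zone_cfg, cal, weight_matrix, weight_table, rng):
        for _ in range(5):
            amps = {au: float(rng.uniform(0, 5)) for au in ("AU1", "AU6", "AU15")}
            active = pf.apply_activation(template, amps, cal)
            s = pf.compute_pain(
                template.landmarks, active, zone_cfg, cal, weight_matrix, weight_table
            )
            assert s.ps == pytest.approx(sum(amps.values()), abs=1e-9)
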