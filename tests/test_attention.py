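import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crabloom import (
    AnalysisConfig,
    BehaviorGenParams,
    SpikeGenParams,
    TreatmentSpec,
    behavioral_decision,
    ephys_metrics_table,
    experiment1_treatments,
    gen_ephys_population,
    gen_escape_trials,
    neural_decision,
    orientation_effect,
    predict_directions,
    timing_comparison,
)
from crabloom.circstats import angular_difference

P90 = TreatmentSpec("Paired90", (0.0, 270.0), (-1.0, -1.0))
P180 = TreatmentSpec("Paired180", (0.0, 180.0), (-1.0, -1.0))
SINGLE = TreatmentSpec("Single", (0.0,), (-1.0,))


class TestPredictDirections:
    def test_single_stimulus_hypotheses_coincide(self):
        sel = predict_directions(SINGLE, "selective")
        div = predict_directions(SINGLE, "divided")
        assert sel.predicted_modes == (180.0,)
        assert div.predicted_modes == (180.0,)

    def test_paired90(self):
        assert set(predict_directions(P90, "selective").predicted_modes) == {
            180.0,
            90.0,
        }
        assert predict_directions(P90, "divided").predicted_modes == (135.0,)

    def test_paired180(self):
        assert set(predict_directions(P180, "selective").predicted_modes) == {
            180.0,
            0.0,
        }
        assert set(predict_directions(P180, "divided").predicted_modes) == {
            90.0,
            270.0,
        }

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(delta=st.floats(0.0, 360.0), hyp=st.sampled_from(
        ["selective", "divided"]))
    def test_rotation_equivariance(self, delta, hyp):
        base = predict_directions(P90, hyp).predicted_modes
        rotated_treatment = TreatmentSpec(
            "Paired90",
            tuple((a + delta) % 360.0 for a in P90.stimulus_azimuths),
            P90.stimulus_contrasts,
        )
        rotated = predict_directions(rotated_treatment, hyp).predicted_modes
        # rotating the stimuli by delta rotates every predicted mode by delta
        got = sorted(round((m - delta) % 360.0, 6) % 360.0 for m in rotated)
        want = sorted(round(m % 360.0, 6) % 360.0 for m in base)
        diffs = [abs(angular_difference(a, b)) for a, b in zip(got, want)]
        assert max(diffs) < 1e-5


class TestBehavioralDecision:
    @pytest.mark.parametrize("mode", ["selective", "divided"])
    def test_recovers_generating_hypothesis(self, mode, exp1_treatments,
                                            fast_config):
        correct = 0
        for seed in range(12):
            params = BehaviorGenParams(attention_mode=mode, seed=seed)
            trials = gen_escape_trials(params, exp1_treatments, 40, 1)
            report = behavioral_decision(trials, fast_config)
            correct += report.behavioral_verdict == mode
        assert correct >= 11

    def test_degenerate_selective_sector_test_uninformative(
            self, exp1_treatments, fast_config):
        params = BehaviorGenParams(
            kappa=1e6, attention_mode="selective", seed=0,
            response_prob_by_treatment=1.0,
        )
        trials = gen_escape_trials(params, exp1_treatments, 30, 1)
        report = behavioral_decision(trials, fast_config)
        assert report.behavioral_verdict == "selective"
        sector = report.statistics["treatments"]["Paired90"]["sector_test"]
        assert sector["p"] == pytest.approx(1.0)

    def test_small_sample_is_inconclusive(self, exp1_treatments, fast_config):
        params = BehaviorGenParams(seed=1)
        trials = gen_escape_trials(params, exp1_treatments, 6, 1)
        report = behavioral_decision(trials, fast_config)
        assert report.behavioral_verdict == "inconclusive"

    def test_diffuse_directions_never_misclassified_badly(
            self, exp1_treatments, fast_config):
        wrong = 0
        for seed in range(10):
            params = BehaviorGenParams(
                kappa=0.3, attention_mode="selective", seed=seed
            )
            trials = gen_escape_trials(params, exp1_treatments, 40, 1)
            verdict = behavioral_decision(trials, fast_config)
            wrong += verdict.behavioral_verdict == "divided"
        assert wrong <= 1


class TestOrientationEffect:
    def test_lateral_bias_drives_escape_choice(self, fast_config):
        params = BehaviorGenParams(
            lateral_bias_strength=5.0, response_prob_by_treatment=1.0, seed=2
        )
        trials = gen_escape_trials(params, [P90], 200, 1)
        out = orientation_effect(trials, fast_config)
        by_bin = out.set_index("orientation_bin")
        # stimulus at 0 deg on the lateral axis -> run to 180
        for b in ("lateral_0", "lateral_180"):
            assert abs(
                angular_difference(by_bin.loc[b, "mean_direction"], 180.0)
            ) < 15.0
        # stimulus at 270 deg on the lateral axis -> run to 90
        for b in ("anteroposterior_90", "anteroposterior_270"):
            assert abs(
                angular_difference(by_bin.loc[b, "mean_direction"], 90.0)
            ) < 15.0

    def test_opposed_stimuli_axial_but_not_raw_directional(self, fast_config):
        params = BehaviorGenParams(
            lateral_bias_strength=0.0, contrast_bias_strength=0.0,
            response_prob_by_treatment=1.0, seed=3,
        )
        trials = gen_escape_trials(params, [P180], 300, 1)
        out = orientation_effect(trials, fast_config)
        ap = out[out["orientation_bin"].str.startswith("anteroposterior")]
        assert (ap["rayleigh_p"] < 0.05).all()  # axial (doubled) test
        assert (ap["rayleigh_p_raw"] > 0.05).all()  # antipodal modes cancel

    def test_no_bias_means_even_choice(self, fast_config):
        params = BehaviorGenParams(
            lateral_bias_strength=0.0, contrast_bias_strength=0.0,
            kappa=1e6, response_prob_by_treatment=1.0, seed=4,
        )
        trials = gen_escape_trials(params, [P90], 400, 1)
        d = trials["escape_direction_deg"].to_numpy()
        orient = trials["body_orientation_deg"].to_numpy()
        for quadrant in range(4):
            sel = (orient >= 90 * quadrant) & (orient < 90 * (quadrant + 1))
            frac = np.mean(np.abs(
                [angular_difference(x, 180.0) for x in d[sel]]) < 1.0)
            assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / sel.sum())


class TestNeuralDecision:
    @pytest.mark.parametrize(
        "rule, verdict", [("max", "select_stronger"), ("sum", "sum")]
    )
    def test_recovers_integration_rule(self, rule, verdict, fast_config):
        hits = 0
        for seed in range(5):
            params = SpikeGenParams(integration_rule=rule, seed=100 + seed)
            trains = gen_ephys_population(params, n_neurons=20,
                                          seed=100 + seed)
            metrics = ephys_metrics_table(trains, fast_config)
            report = neural_decision(metrics, fast_config)
            hits += report.neural_verdict == verdict
        assert hits >= 4

    def test_equal_weights_make_rules_indistinguishable(self, fast_config):
        params = SpikeGenParams(
            integration_rule="max", receptive_weight_secondary=1.0, seed=5
        )
        trains = gen_ephys_population(
            params, n_neurons=10, weight_jitter=0.0, seed=5
        )
        metrics = ephys_metrics_table(trains, fast_config)
        report = neural_decision(metrics, fast_config)
        assert report.neural_verdict == "inconclusive"

    def test_few_neurons_inconclusive(self, fast_config):
        params = SpikeGenParams(seed=6)
        trains = gen_ephys_population(params, n_neurons=3, seed=6)
        metrics = ephys_metrics_table(trains, fast_config)
        report = neural_decision(metrics, fast_config)
        assert report.neural_verdict == "inconclusive"
        assert report.statistics["n_neurons"] == 3


class TestTimingComparison:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(11)
        base = rng.normal(2.5, 0.3, 20) ** 2
        df = pd.DataFrame(
            {
                "crab_id": np.tile([f"c{i}" for i in range(20)], 2),
                "treatment": ["A"] * 20 + ["B"] * 20,
                "time_to_collision_s": np.concatenate([base, base]),
            }
        )
        res = timing_comparison(df, n_perm=999, seed=0)
        assert res["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_exact_enumeration_matches_brute_force(self):
        import itertools

        rng = np.random.default_rng(12)
        vals = rng.normal(2.0, 0.4, 12) ** 2
        df = pd.DataFrame(
            {
                "crab_id": np.repeat([f"c{i}" for i in range(6)], 2),
                "treatment": ["A", "B"] * 6,
                "time_to_collision_s": vals,
            }
        )
        res = timing_comparison(df, n_perm=None, seed=0)
        sq = np.sqrt(vals)
        lab = np.array([True, False] * 6)
        obs = sq[lab].mean() - sq[~lab].mean()
        count = 0
        for flips in itertools.product([False, True], repeat=6):
            m = lab.copy()
            for i, f in enumerate(flips):
                if f:
                    m[2 * i: 2 * i + 2] = ~m[2 * i: 2 * i + 2]
            if abs(sq[m].mean() - sq[~m].mean()) >= abs(obs) - 1e-12:
                count += 1
        assert res["p_raw"].iloc[0] == pytest.approx(count / 64)

    def test_detects_contrast_timing_shift(self):
        # LC responses 0.3 sqrt-s later than HC, 20 crabs, paired design
        detections = 0
        seeds = 40
        for seed in range(seeds):
            params = BehaviorGenParams(
                response_prob_by_treatment=1.0,
                timing_mean_sqrt={"SingleHC": 1.6, "SingleLC": 1.3},
                seed=seed,
            )
            treats = [
                TreatmentSpec("SingleHC", (0.0,), (-1.0,)),
                TreatmentSpec("SingleLC", (0.0,), (-0.4,)),
            ]
            trials = gen_escape_trials(params, treats, 20, 1)
            res = timing_comparison(trials, n_perm=499, seed=seed)
            detections += res["p_raw"].iloc[0] < 0.05
        assert detections / seeds >= 0.8

    def test_holm_never_decreases_p(self, selective_trials):
        res = timing_comparison(selective_trials, n_perm=499, seed=1)
        assert (res["p_holm"] >= res["p_raw"] - 1e-12).all()

    def test_sparse_group_skipped(self):
        df = pd.DataFrame(
            {
                "crab_id": ["c1", "c1", "c2", "c2"],
                "treatment": ["A", "B", "A", "B"],
                "time_to_collision_s": [4.0, 5.0, 4.5, 5.5],
            }
        )
        res = timing_comparison(df, n_perm=99, seed=0)
        assert res.empty
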