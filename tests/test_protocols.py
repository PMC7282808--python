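"""Synthetic-data generators and the simulation protocol suite."""

import math

import numpy as np
import pandas as pd
import pytest

from statemap._angles import circ_mean
from statemap.crp import Concentration, Partition
from statemap.inference import NOVEL, state_evidence_ratio
from statemap.observations import ObservationSet
from statemap.protocols import (
    PROTOCOLS,
    AlternationLearningConfig,
    CueRotationConfig,
    DistributionSpec,
    MorphTestConfig,
    ScheduleHypothesesConfig,
    generate_observations,
    make_config,
    max_margin_split,
    run_alternation_learning,
    run_cue_rotation,
    run_direction_foraging,
    run_morph_test,
    run_protocol,
    run_schedule_hypotheses,
    split_labels,
)
from statemap.observation_models import GaussianModel


def values(table: pd.DataFrame, quantity: str, condition: str | None = None) -> np.ndarray:
    mask = table.quantity == quantity
    if condition is not None:
        mask &= table.condition == condition
    return table.loc[mask, "value"].to_numpy()


class TestGenerators:
    def test_zero_sd_gaussian_is_deterministic(self):
        obs = generate_observations(DistributionSpec("gaussian", (0.0, 0.0), (0.0, 0.0)), 5, 1)
        np.testing.assert_array_equal(obs.data, np.zeros((5, 2)))
        assert obs.all_linear

    def test_uniform_circular_has_tiny_resultant(self):
        obs = generate_observations(DistributionSpec("uniform_circular", (0.0,)), 10_000, 2)
        resultant = np.abs(np.exp(1j * np.deg2rad(obs.data[:, 0])).mean())
        assert resultant < 0.03  # E[R] ~ sqrt(pi/(4n)) ~ 0.009
        assert obs.all_circular

    def test_wrapped_normal_moments_recovered(self):
        obs = generate_observations(DistributionSpec("wrapped_normal", (0.0,), (18.0,)), 10_000, 3)
        z = np.exp(1j * np.deg2rad(obs.data[:, 0]))
        assert abs(circ_mean(obs.data[:, 0])) < 1.0
        circ_sd = np.rad2deg(math.sqrt(-2 * math.log(np.abs(z.mean()))))
        assert abs(circ_sd - 18.0) < 1.0

    def test_vonmises_zero_kappa_is_uniform(self):
        obs = generate_observations(DistributionSpec("vonmises", (0.0,), (0.0,)), 10_000, 4)
        resultant = np.abs(np.exp(1j * np.deg2rad(obs.data[:, 0])).mean())
        assert resultant < 0.03

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError):
            DistributionSpec("cauchy", (0.0,), (1.0,))


class TestMaxMarginSplit:
    def test_antipodal_pair(self):
        theta = max_margin_split(ObservationSet.circular([0.0, 180.0]))
        assert theta == 90.0

    def test_two_vonmises_clusters(self, rng):
        angles = np.concatenate(
            [np.rad2deg(rng.vonmises(0.0, 10.0, 20)), np.rad2deg(rng.vonmises(np.pi, 10.0, 20))]
        ) % 360
        theta = max_margin_split(ObservationSet.circular(angles))
        assert min(abs(theta - 90.0), abs(theta - 0.0) + 1e9) < 10.0

    def test_tie_breaks_to_smallest_angle(self):
        theta = max_margin_split(ObservationSet.circular([0.0, 90.0, 180.0, 270.0]))
        assert theta == 45.0

    def test_split_labels_partition_the_circle(self):
        obs = ObservationSet.circular([10.0, 170.0, 190.0, 350.0])
        part = split_labels(obs, 0.0)
        assert part == Partition([0, 0, 1, 1])

    def test_needs_two_observations(self):
        with pytest.raises(ValueError):
            max_margin_split(ObservationSet.circular([0.0]))


class TestProtocolContracts:
    @pytest.mark.parametrize("name", sorted(PROTOCOLS))
    def test_deterministic_given_seed(self, name):
        a = run_protocol(name, seed=7)
        b = run_protocol(name, seed=7)
        pd.testing.assert_frame_equal(a, b)
        assert list(a.columns) == ["protocol", "condition", "step", "quantity", "value", "seed"]
        assert (a.protocol == name).all()
        assert (a.seed == 7).all()

    def test_unknown_protocol(self):
        with pytest.raises(KeyError):
            run_protocol("warp_drive")

    def test_make_config_validates_fields(self):
        cfg = make_config("alternation_learning", {"alphas": [0.5]})
        assert cfg.alphas == (0.5,)
        with pytest.raises(ValueError):
            make_config("alternation_learning", {"bogus": 1})


class TestAlternationLearning:
    def test_distinct_contexts_end_in_two_states(self):
        final = [
            values(run_alternation_learning(seed=s), "log_odds_one_state_vs_two_states")[-1]
            for s in range(10)
        ]
        assert all(v < 0 for v in final)

    def test_identical_contexts_end_in_one_state(self):
        cfg = AlternationLearningConfig(means=(0.0, 0.0))
        final = [
            values(run_alternation_learning(cfg, seed=s), "log_odds_one_state_vs_two_states")[-1]
            for s in range(10)
        ]
        assert all(v > 0 for v in final)

    def test_larger_alpha_crosses_earlier(self):
        """Crossing step (first pair favoring two states) shrinks with alpha."""
        cfg = AlternationLearningConfig(alphas=(0.01, 0.1, 1.0), n_pairs=25)
        crossings = {a: [] for a in cfg.alphas}
        for s in range(15):
            t = run_alternation_learning(cfg, seed=s)
            for a in cfg.alphas:
                v = values(t, "log_odds_one_state_vs_two_states", f"alpha={a:g}")
                below = np.nonzero(v < 0)[0]
                crossings[a].append(below[0] if below.size else len(v))
        med = [np.median(crossings[a]) for a in cfg.alphas]
        assert med[0] >= med[1] >= med[2]
        assert med[0] > med[2]


class TestDirectionForaging:
    def test_directional_condition_prefers_two_states(self):
        signs = []
        for s in range(8):
            t = run_direction_foraging(seed=s)
            directional = values(t, "log_odds_two_states_vs_one_state", "directional")[0]
            uniform = values(t, "log_odds_two_states_vs_one_state", "uniform")[0]
            signs.append(directional > uniform)
            assert uniform < 0  # unstructured directions: one state
        assert all(signs)


class TestCueRotation:
    def test_clean_rotation_tracks_the_card(self):
        t = run_cue_rotation(CueRotationConfig(manipulations=("180_clean",)), seed=5)
        off = values(t, "best_offset_deg")[0]
        assert abs(abs(off) - 180) <= 15
        assert values(t, "log_odds_same_vs_novel")[0] > 0

    def test_dirty_45_compromises_between_cues(self):
        offs = [
            values(run_cue_rotation(CueRotationConfig(manipulations=("45_dirty",)), seed=s),
                   "best_offset_deg")[0]
            for s in range(6)
        ]
        assert 0 < np.median(offs) < 45


class TestMorphTest:
    def test_square_probe_positive_and_training_steepens(self):
        """Near-square probes stay with the square state, and training
        sharpens the curve at both ends (on average over seeds)."""
        odds5, odds25 = [], []
        for s in range(10):
            t = run_morph_test(seed=s)
            assert values(t, "log_odds_same_as_square", "n_train=5")[0] > 0
            assert values(t, "log_odds_same_as_square", "n_train=25")[0] > 0
            odds5.append(values(t, "log_odds_same_as_square", "n_train=5"))
            odds25.append(values(t, "log_odds_same_as_square", "n_train=25"))
        mean5, mean25 = np.mean(odds5, axis=0), np.mean(odds25, axis=0)
        assert mean25[0] > mean5[0]  # stronger same-as-square at the square end
        assert mean25[-1] < mean5[-1]  # stronger rejection at the circle end

    def test_center_probe_symmetric_under_relabeling(self, rng):
        """With symmetric training, the S-vs-D odds at probe 0 do not depend on
        which generator is called the square."""
        from statemap.inference import hypothesis_set_log_odds
        from statemap.protocols import _morph_hypotheses

        n = 10
        z = rng.normal(0.0, 0.3, n)
        data = np.where(np.arange(n) % 2 == 0, -1.0, 1.0) + z
        obs = ObservationSet.linear(data)
        flipped = ObservationSet.linear(-data)  # swaps the square/circle roles
        model = GaussianModel.default(1)
        set_s, set_d = _morph_hypotheses(n)
        a = hypothesis_set_log_odds(obs, [0.0], set_s, set_d, Concentration(0.1), model)
        b = hypothesis_set_log_odds(flipped, [0.0], set_s, set_d, Concentration(0.1), model)
        assert math.isclose(a.log_odds, b.log_odds, abs_tol=1e-9)


class TestScheduleHypotheses:
    def test_posteriors_normalized_and_alpha_ordered(self):
        t = run_schedule_hypotheses(seed=2)
        cfg = ScheduleHypothesesConfig()
        together, separate = [], []
        for a in cfg.alphas:
            cond = f"alpha={a:g}"
            probs = {q: values(t, q, cond)[0] for q in
                     ("p_all_separate", "p_circles_together", "p_all_together")}
            assert math.isclose(sum(probs.values()), 1.0, abs_tol=1e-9)
            together.append(probs["p_all_together"])
            separate.append(probs["p_all_separate"])
        assert all(np.diff(together) <= 1e-12)  # small alpha -> merged
        assert all(np.diff(separate) >= -1e-12)  # large alpha -> separate

    def test_tight_clusters_group_by_environment(self):
        """As the session noise vanishes, the shape/color structure keeps the
        two circles together and the square separate (at moderate alpha)."""
        t = run_schedule_hypotheses(ScheduleHypothesesConfig(sd=1e-3, alphas=(0.1,)), seed=2)
        probs = {q: values(t, q, "alpha=0.1")[0] for q in
                 ("p_all_separate", "p_circles_together", "p_all_together")}
        assert probs["p_circles_together"] == max(probs.values())

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            run_schedule_hypotheses(ScheduleHypothesesConfig(schedule=()), seed=0)


class TestCueVariability:
    def test_training_variability_flips_the_inference(self):
        t = run_protocol("cue_variability", seed=4)
        assert values(t, "log_odds_same_vs_novel", "cyan")[0] > 0
        assert values(t, "log_odds_same_vs_novel", "magenta")[0] < 0

    def test_feature_role_swap_symmetry(self, rng):
        """Transposing both the training draws and the probe swaps the two
        conditions' evidence ratios exactly."""
        z = rng.normal(size=(20, 2))
        conc = Concentration(0.1)
        model = GaussianModel.default(2)

        def ratio(mean, sd, probe, draws):
            train = ObservationSet.linear(np.asarray(mean) + np.asarray(sd) * draws)
            return state_evidence_ratio(
                probe, train, Partition.single_state(20), conc, model, 0, NOVEL
            ).log_odds

        cyan = ratio((-5, 0), (2, 0.1), [-1.0, 0.0], z)
        cyan_t = ratio((0, -5), (0.1, 2), [0.0, -1.0], z[:, ::-1])
        assert math.isclose(cyan, cyan_t, rel_tol=1e-9)
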