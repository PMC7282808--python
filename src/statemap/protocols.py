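"""Simulation protocols: synthetic-data generators and the experiment suite.

Each protocol is a pure function of a config plus a seed and returns a tidy
long-format table (columns: protocol, condition, step, quantity, value,
seed).  One "observation" stands for one recording session.  Defaults
reproduce the study conditions of the corresponding simulated experiment:

* ``cue_constellation``   -- 4 Gaussian cue features, probes with 0-4 cues
  changed; same-vs-novel state evidence ratio per probe.
* ``alternation_learning`` -- alternating 1-D sessions from two Gaussians;
  partition evidence ratio (one state vs alternating two states) after each
  pair.  Covers both the "learning to distinguish" setting (means -1/+1)
  and the "map stabilization" setting (both means 0), and a list of
  concentration values alpha.
* ``direction_foraging``  -- circular running-direction observations,
  uniform vs bimodal Von Mises; maximum-margin split, then two-state vs
  one-state partition evidence ratio.
* ``cue_rotation``        -- cue-card rotation with reference-direction
  (offset) inference, clean and dirty variants.
* ``morph_test``          -- intermediate "morph" probes between two trained
  extremes; log odds of the same-as-square hypothesis set after 5 and 25
  training sessions.
* ``schedule_hypotheses`` -- 2-D shape/color sessions on a configurable
  schedule; normalized posterior over three named partitions per alpha.
* ``cue_variability``     -- two training conditions differing in which
  feature is variable; same probe, same-vs-novel evidence ratio each.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._angles import circ_dist, wrap_360
from .crp import Concentration, Partition, partition_log_prior
from .inference import (
    NOVEL,
    Hypothesis,
    hypothesis_set_log_odds,
    partition_evidence_ratio,
    partition_log_posterior,
    state_evidence_ratio,
)
from .observation_models import (
    GaussianModel,
    IntegrationGrid,
    NIWHyper,
    VonMisesModel,
    VonMisesNGHyper,
    gaussian_chain_log_predictives,
)
from .observations import CIRCULAR, LINEAR, ObservationSet
from .rotation import rotation_assignment

__all__ = [
    "DistributionSpec",
    "generate_observations",
    "max_margin_split",
    "split_labels",
    "PROTOCOLS",
    "run_protocol",
    "CueConstellationConfig",
    "run_cue_constellation",
    "AlternationLearningConfig",
    "run_alternation_learning",
    "DirectionForagingConfig",
    "run_direction_foraging",
    "CueRotationConfig",
    "run_cue_rotation",
    "MorphTestConfig",
    "run_morph_test",
    "ScheduleHypothesesConfig",
    "run_schedule_hypotheses",
    "CueVariabilityConfig",
    "run_cue_variability",
]

RESULT_COLUMNS = ["protocol", "condition", "step", "quantity", "value", "seed"]


# ---------------------------------------------------------------------------
# Synthetic-data generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistributionSpec:
    """Per-session observation distribution.

    families: ``gaussian`` (mean/sd per linear feature), ``vonmises``
    (mean deg / concentration kappa), ``wrapped_normal`` (mean deg / sd deg),
    ``uniform_circular`` (dims only).
    """

    family: str
    mean: tuple = ()
    scale: tuple = ()
    dims: int | None = None

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "vonmises", "wrapped_normal", "uniform_circular"):
            raise ValueError(f"unknown family {self.family!r}")
        mean = tuple(np.atleast_1d(np.asarray(self.mean, dtype=float)))
        scale = tuple(np.atleast_1d(np.asarray(self.scale, dtype=float)))
        if self.family == "uniform_circular":
            if self.dims is None:
                object.__setattr__(self, "dims", max(1, len(mean)))
        else:
            if len(scale) == 1 and len(mean) > 1:
                scale = scale * len(mean)
            if len(mean) != len(scale):
                raise ValueError("mean and scale must have matching lengths")
            if self.family in ("gaussian", "wrapped_normal") and any(s < 0 for s in scale):
                raise ValueError("standard deviations must be non-negative")
            if self.family == "vonmises" and any(s < 0 for s in scale):
                raise ValueError("kappa must be non-negative")
            object.__setattr__(self, "dims", len(mean))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "scale", scale)

    @property
    def is_circular(self) -> bool:
        return self.family != "gaussian"


def generate_observations(spec: DistributionSpec, n: int, seed) -> ObservationSet:
    """Reproducible draws from a distribution spec.

    Wrapped-normal draws are plain normal draws (degrees) wrapped into
    [0, 360).  ``seed`` may be an int or a numpy Generator.
    """
    rng = np.random.default_rng(seed)
    d = spec.dims
    if spec.family == "gaussian":
        data = rng.normal(spec.mean, spec.scale, size=(n, d))
        return ObservationSet(data, (LINEAR,) * d)
    if spec.family == "wrapped_normal":
        data = wrap_360(rng.normal(spec.mean, spec.scale, size=(n, d)))
    elif spec.family == "vonmises":
        data = wrap_360(
            np.rad2deg(rng.vonmises(np.deg2rad(np.asarray(spec.mean)), spec.scale, size=(n, d)))
        )
    else:  # uniform_circular
        data = rng.uniform(0.0, 360.0, size=(n, d))
    return ObservationSet(data, (CIRCULAR,) * d)


def generate_alternating(specs: Sequence[DistributionSpec], n: int, seed) -> ObservationSet:
    """n observations cycling through a sequence of specs (session schedule)."""
    rng = np.random.default_rng(seed)
    rows = [generate_observations(specs[t % len(specs)], 1, rng).data[0] for t in range(n)]
    kinds = (CIRCULAR,) * specs[0].dims if specs[0].is_circular else (LINEAR,) * specs[0].dims
    return ObservationSet(np.array(rows), kinds)


def max_margin_split(obs: ObservationSet, step_deg: float = 1.0) -> float:
    """Boundary angle of the diameter farthest from all circular observations.

    Splits directions into the two half-circles bounded by {theta,
    theta + 180}; returns the theta in [0, 180) maximizing the minimum
    angular distance from any observation to the boundary.  Ties break
    toward the smallest qualifying theta.
    """
    if not (obs.all_circular and obs.n_features == 1):
        raise ValueError("max_margin_split requires 1-D circular observations")
    if obs.n_obs < 2:
        raise ValueError("need at least 2 observations to split")
    angles = obs.data[:, 0]
    thetas = np.arange(0.0, 180.0, step_deg)
    d1 = circ_dist(angles[None, :], thetas[:, None])
    d2 = circ_dist(angles[None, :], thetas[:, None] + 180.0)
    margin = np.minimum(d1, d2).min(axis=1)
    return float(thetas[int(np.argmax(margin))])


def split_labels(obs: ObservationSet, theta: float) -> Partition:
    """Two-state partition by the half-circle (theta, theta+180] membership."""
    rel = wrap_360(obs.data[:, 0] - theta)
    return Partition([0 if 0.0 < r <= 180.0 else 1 for r in rel])


# ---------------------------------------------------------------------------
# Result-table plumbing
# ---------------------------------------------------------------------------


def _table(protocol: str, seed: int, rows: list[tuple]) -> pd.DataFrame:
    return pd.DataFrame(
        [(protocol, c, s, q, float(v), seed) for (c, s, q, v) in rows],
        columns=RESULT_COLUMNS,
    )


# ---------------------------------------------------------------------------
# Cue constellations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CueConstellationConfig:
    n_features: int = 4
    mean: float = 0.0
    sd: float = 0.2
    n_train: int = 20
    probes: tuple = ((0, 0, 0, 0), (1, 0, 0, 0), (1, 0, 0, 1), (1, 1, 1, 1))
    alpha: float = 0.1


def run_cue_constellation(config: CueConstellationConfig | None = None, *, seed: int = 0) -> pd.DataFrame:
    """Same-vs-novel state evidence ratio for probes with 0..D cues changed."""
    cfg = config or CueConstellationConfig()
    spec = DistributionSpec("gaussian", (cfg.mean,) * cfg.n_features, (cfg.sd,) * cfg.n_features)
    train = generate_observations(spec, cfg.n_train, seed)
    partition = Partition.single_state(cfg.n_train)
    conc = Concentration(cfg.alpha)
    model = GaussianModel.default(cfg.n_features)
    rows = []
    for i, probe in enumerate(cfg.probes):
        probe = np.asarray(probe, dtype=float)
        if probe.size != cfg.n_features:
            raise ValueError("probe dimensionality must match n_features")
        res = state_evidence_ratio(probe, train, partition, conc, model, 0, NOVEL)
        label = "probe=" + ",".join(f"{v:g}" for v in probe)
        rows.append((label, i, "log_odds_same_vs_novel", res.log_odds))
    return _table("cue_constellation", seed, rows)


# ---------------------------------------------------------------------------
# Alternating-session learning (distinct means) / stabilization (equal means)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlternationLearningConfig:
    means: tuple = (-1.0, 1.0)
    sd: float = 0.3
    n_pairs: int = 20
    alphas: tuple = (0.1,)


def run_alternation_learning(config: AlternationLearningConfig | None = None, *, seed: int = 0) -> pd.DataFrame:
    """Partition evidence ratio (one state vs alternating two states) per pair.

    Positive values favor the single-state hypothesis (no remapping);
    negative values favor two alternating states (remapping).
    """
    cfg = config or AlternationLearningConfig()
    specs = [DistributionSpec("gaussian", (m,), (cfg.sd,)) for m in cfg.means]
    obs = generate_alternating(specs, 2 * cfg.n_pairs, seed)
    hyper = NIWHyper.default(1)
    # chain-of-predictive prefix sums: the full sequence for the one-state
    # hypothesis, each alternating subsequence for the two-state hypothesis
    lik_one = np.cumsum(gaussian_chain_log_predictives(hyper, obs))
    lik_a = np.cumsum(gaussian_chain_log_predictives(hyper, obs.select(range(0, obs.n_obs, 2))))
    lik_b = np.cumsum(gaussian_chain_log_predictives(hyper, obs.select(range(1, obs.n_obs, 2))))
    rows = []
    for alpha in cfg.alphas:
        conc = Concentration(alpha)
        for p in range(1, cfg.n_pairs + 1):
            one = Partition.single_state(2 * p)
            two = Partition.alternating(2 * p)
            ratio = (
                partition_log_prior(one, conc)
                + lik_one[2 * p - 1]
                - partition_log_prior(two, conc)
                - lik_a[p - 1]
                - lik_b[p - 1]
            )
            rows.append((f"alpha={alpha:g}", p, "log_odds_one_state_vs_two_states", ratio))
    return _table("alternation_learning", seed, rows)


# ---------------------------------------------------------------------------
# Directional vs random foraging (circular running direction)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DirectionForagingConfig:
    n_obs: int = 10
    kappa: float = 10.0
    means: tuple = (0.0, 180.0)
    alpha: float = 0.1
    grid: IntegrationGrid = field(default_factory=IntegrationGrid)


def run_direction_foraging(config: DirectionForagingConfig | None = None, *, seed: int = 0) -> pd.DataFrame:
    """Two-state (max-margin split) vs one-state evidence per condition."""
    cfg = config or DirectionForagingConfig()
    rng = np.random.default_rng(seed)
    conditions = {
        "uniform": generate_observations(DistributionSpec("uniform_circular", (0.0,)), cfg.n_obs, rng),
        "directional": generate_alternating(
            [DistributionSpec("vonmises", (m,), (cfg.kappa,)) for m in cfg.means], cfg.n_obs, rng
        ),
    }
    model = VonMisesModel(VonMisesNGHyper(), cfg.grid)
    conc = Concentration(cfg.alpha)
    rows = []
    for name, obs in conditions.items():
        theta = max_margin_split(obs)
        two = Hypothesis("two_states", split_labels(obs, theta))
        one = Hypothesis("one_state", Partition.single_state(obs.n_obs))
        res = partition_evidence_ratio(obs, two, one, conc, model)
        rows.append((name, 0, "boundary_angle_deg", theta))
        rows.append((name, 0, "log_odds_two_states_vs_one_state", res.log_odds))
    return _table("direction_foraging", seed, rows)


# ---------------------------------------------------------------------------
# Cue rotation with reference-direction inference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CueRotationConfig:
    n_train: int = 10
    cue_sd: float = 18.0
    n_extra: int = 5
    extra_sd: float = 54.0
    manipulations: tuple = ("180_clean", "180_dirty", "45_dirty")
    offset_step: float = 1.0
    alpha: float = 0.1
    grid: IntegrationGrid = field(default_factory=IntegrationGrid)


def _parse_manipulation(name: str) -> tuple[float, bool]:
    rot, _, variant = name.partition("_")
    if variant not in ("clean", "dirty"):
        raise ValueError(f"unknown manipulation {name!r}")
    return float(rot), variant == "dirty"


def run_cue_rotation(config: CueRotationConfig | None = None, *, seed: int = 0) -> pd.DataFrame:
    """Best rotational offset and same-vs-novel evidence per manipulation.

    Clean: a single cue-card feature (wrapped normal, mean 0, sd 18 deg).
    Dirty: the cue card plus ``n_extra`` lower-fidelity cues whose means are
    drawn once per run uniformly on the circle (sd 54 deg) and repeated in
    the probe.  The probe rotates only the cue card.
    """
    cfg = config or CueRotationConfig()
    children = np.random.SeedSequence(seed).spawn(len(cfg.manipulations))
    model = VonMisesModel(VonMisesNGHyper(), cfg.grid)
    conc = Concentration(cfg.alpha)
    rows = []
    for name, child in zip(cfg.manipulations, children):
        rotation, dirty = _parse_manipulation(name)
        rng = np.random.default_rng(child)
        if dirty:
            extra_means = rng.uniform(0.0, 360.0, cfg.n_extra)
            means = (0.0, *extra_means)
            sds = (cfg.cue_sd, *([cfg.extra_sd] * cfg.n_extra))
            probe = np.array([rotation, *extra_means])
        else:
            means, sds = (0.0,), (cfg.cue_sd,)
            probe = np.array([rotation])
        train = generate_observations(
            DistributionSpec("wrapped_normal", means, sds), cfg.n_train, rng
        )
        result = rotation_assignment(
            probe, train, Partition.single_state(cfg.n_train), conc, model, cfg.offset_step
        )
        rows.append((name, 0, "best_offset_deg", result.per_state_offset[0]))
        rows.append((name, 0, "log_odds_same_vs_novel", result.evidence.log_odds))
    return _table("cue_rotation", seed, rows)


# ---------------------------------------------------------------------------
# Morph probes between two trained extremes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MorphTestConfig:
    means: tuple = (-1.0, 1.0)  # (square, circle) on the abstract shape axis
    sd: float = 0.3
    n_train_list: tuple = (5, 25)
    probes: tuple = tuple(np.round(np.linspace(-1.0, 1.0, 9), 6))
    alpha: float = 0.1


def _morph_hypotheses(n_train: int) -> tuple[list[Hypothesis], list[Hypothesis]]:
    """S = morph shares the square's state; D = it does not.

    Training alternates square (-1), circle (+1), ... so in the two-state
    partition state 0 holds the square sessions.
    """
    one = Partition.single_state(n_train)
    two = Partition.alternating(n_train)
    set_s = [
        Hypothesis("S1:one_state,same", one, 0),
        Hypothesis("S2:two_states,square", two, 0),
    ]
    set_d = [
        Hypothesis("D1:one_state,novel", one, NOVEL),
        Hypothesis("D2:two_states,circle", two, 1),
        Hypothesis("D3:two_states,novel", two, NOVEL),
    ]
    return set_s, set_d


def run_morph_test(config: MorphTestConfig | None = None, *, seed: int = 0) -> pd.DataFrame:
    """Log odds that a morph probe shares the square's hidden state."""
    cfg = config or MorphTestConfig()
    specs = [DistributionSpec("gaussian", (m,), (cfg.sd,)) for m in cfg.means]
    obs = generate_alternating(specs, max(cfg.n_train_list), seed)
    model = GaussianModel.default(1)
    conc = Concentration(cfg.alpha)
    rows = []
    for n_train in cfg.n_train_list:
        head = obs.head(n_train)
        set_s, set_d = _morph_hypotheses(n_train)
        for i, probe in enumerate(cfg.probes):
            res = hypothesis_set_log_odds(
                head, np.array([probe]), set_s, set_d, conc, model,
                names=("same_as_square", "not_square"),
            )
            rows.append((f"n_train={n_train}", i, "probe_value", probe))
            rows.append((f"n_train={n_train}", i, "log_odds_same_as_square", res.log_odds))
    return _table("morph_test", seed, rows)


# ---------------------------------------------------------------------------
# Session-schedule hypotheses (shape/color sessions, alpha sweep)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScheduleHypothesesConfig:
    # features: (shape, color); +1 = circle / white, -1 = square / morph-box
    environments: tuple = (
        ("white_circle", (1.0, 1.0)),
        ("morph_circle", (1.0, -1.0)),
        ("morph_square", (-1.0, -1.0)),
    )
    sd: float = 0.1
    schedule: tuple = (
        "white_circle", "morph_circle", "white_circle",
        "morph_circle", "white_circle", "morph_circle",
        "morph_square", "morph_square", "morph_square",
    )
    alphas: tuple = (1e-12, 1e-6, 0.1, 10.0)


def run_schedule_hypotheses(config: ScheduleHypothesesConfig | None = None, *, seed: int = 0) -> pd.DataFrame:
    """Normalized posterior over three named partitions, per alpha.

    Hypotheses: every environment its own state ("all_separate"); the two
    circles share a state and the square is separate ("circles_together");
    one state for everything ("all_together").
    """
    cfg = config or ScheduleHypothesesConfig()
    if not cfg.schedule:
        raise ValueError("the session schedule must be non-empty")
    env_means = dict(cfg.environments)
    unknown = [s for s in cfg.schedule if s not in env_means]
    if unknown:
        raise ValueError(f"schedule names unknown environments: {unknown}")
    rng = np.random.default_rng(seed)
    rows_data = [
        generate_observations(
            DistributionSpec("gaussian", env_means[s], (cfg.sd,) * len(env_means[s])), 1, rng
        ).data[0]
        for s in cfg.schedule
    ]
    obs = ObservationSet(np.array(rows_data))
    env_index = {name: i for i, (name, _) in enumerate(cfg.environments)}
    by_env = [env_index[s] for s in cfg.schedule]
    circle_env = {
        name: (0 if "circle" in name else 1) for name, _ in cfg.environments
    }
    partitions = {
        "all_separate": Partition(by_env),
        "circles_together": Partition([circle_env[s] for s in cfg.schedule]),
        "all_together": Partition.single_state(len(cfg.schedule)),
    }
    model = GaussianModel.default(obs.n_features)
    rows = []
    for alpha in cfg.alphas:
        conc = Concentration(alpha)
        scores = {
            name: partition_log_posterior(obs, part, conc, model)
            for name, part in partitions.items()
        }
        vals = np.array(list(scores.values()))
        probs = np.exp(vals - vals.max())
        probs /= probs.sum()
        for (name, _), p in zip(scores.items(), probs):
            rows.append((f"alpha={alpha:g}", 0, f"p_{name}", p))
    return _table("schedule_hypotheses", seed, rows)


# ---------------------------------------------------------------------------
# Cue variability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CueVariabilityConfig:
    conditions: tuple = (
        ("cyan", (-5.0, 0.0), (2.0, 0.1)),
        ("magenta", (0.0, 0.0), (0.1, 2.0)),
    )
    n_train: int = 20
    probe: tuple = (-1.0, 0.0)
    alpha: float = 0.1


def run_cue_variability(config: CueVariabilityConfig | None = None, *, seed: int = 0) -> pd.DataFrame:
    """Same-vs-novel evidence for one probe under two training variabilities."""
    cfg = config or CueVariabilityConfig()
    children = np.random.SeedSequence(seed).spawn(len(cfg.conditions))
    conc = Concentration(cfg.alpha)
    probe = np.asarray(cfg.probe, dtype=float)
    model = GaussianModel.default(probe.size)
    rows = []
    for (name, mean, sd), child in zip(cfg.conditions, children):
        train = generate_observations(DistributionSpec("gaussian", mean, sd), cfg.n_train, child)
        res = state_evidence_ratio(
            probe, train, Partition.single_state(cfg.n_train), conc, model, 0, NOVEL
        )
        rows.append((name, 0, "log_odds_same_vs_novel", res.log_odds))
    return _table("cue_variability", seed, rows)


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

PROTOCOLS: dict[str, tuple[type, Callable]] = {
    "cue_constellation": (CueConstellationConfig, run_cue_constellation),
    "alternation_learning": (AlternationLearningConfig, run_alternation_learning),
    "direction_foraging": (DirectionForagingConfig, run_direction_foraging),
    "cue_rotation": (CueRotationConfig, run_cue_rotation),
    "morph_test": (MorphTestConfig, run_morph_test),
    "schedule_hypotheses": (ScheduleHypothesesConfig, run_schedule_hypotheses),
    "cue_variability": (CueVariabilityConfig, run_cue_variability),
}


def make_config(protocol: str, overrides: dict | None = None):
    """Build a protocol config from defaults plus overrides (validated)."""
    if protocol not in PROTOCOLS:
        raise KeyError(
            f"unknown protocol {protocol!r}; valid protocols: {', '.join(sorted(PROTOCOLS))}"
        )
    cfg_cls, _ = PROTOCOLS[protocol]
    cfg = cfg_cls()
    if overrides:
        valid = {f.name for f in fields(cfg_cls)}
        for key, value in overrides.items():
            if key == "alpha" and key not in valid and "alphas" in valid:
                key, value = "alphas", (value,)
            if key not in valid:
                raise ValueError(f"unknown config field {key!r} for protocol {protocol!r}")
            if isinstance(value, list):
                value = tuple(value)
            cfg = replace(cfg, **{key: value})
    return cfg


def run_protocol(protocol: str, config=None, *, seed: int = 0) -> pd.DataFrame:
    """Run a registered protocol by name."""
    if protocol not in PROTOCOLS:
        raise KeyError(
            f"unknown protocol {protocol!r}; valid protocols: {', '.join(sorted(PROTOCOLS))}"
        )
    _, runner = PROTOCOLS[protocol]
    return runner(config, seed=seed)
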