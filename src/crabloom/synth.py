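"""Synthetic behavioural trials and spike trains.

The generators emulate the statistical structure of treadmill escape
experiments and intracellular recordings from looming-sensitive neurons,
so the whole analysis pipeline can be exercised and validated without
access to the original recordings.

Behaviour: escape directions are von Mises draws around the mode(s)
predicted by the attention mechanism being simulated -- under selective
attention one stimulus is chosen per trial (with a choice bias towards
stimuli aligned with the crab's lateral body axis and towards higher
contrast) and the crab runs directly away from it; under divided
attention the crab runs in the direction that maximises distance from
both stimuli.  Response timing is Gaussian on the square-root
time-to-collision scale with a per-crab random offset.

Neurons: spike trains are inhomogeneous Poisson processes (Lewis
thinning) whose rate is a spontaneous baseline plus a gain times the
stimulus angular expansion rate, weighted by receptive-field position
and contrast, with a configurable rule (max / sum / average) for
combining two simultaneous stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .circstats import circ_summary
from .stimulus import (
    InvalidParameterError,
    LoomingStimulus,
    collision_time,
    expansion_rate,
)

# ---------------------------------------------------------------------------
# treatments


@dataclass(frozen=True)
class TreatmentSpec:
    """One stimulus configuration of the escape experiments."""

    name: str
    stimulus_azimuths: tuple[float, ...]
    stimulus_contrasts: tuple[float, ...]

    _KNOWN = (
        "Single",
        "Paired90",
        "Paired180",
        "SingleLC",
        "SingleHC",
        "PairedContrast90",
        "PairedContrast180",
    )

    def __post_init__(self) -> None:
        az = tuple(float(a) % 360.0 for a in self.stimulus_azimuths)
        c = tuple(float(x) for x in self.stimulus_contrasts)
        object.__setattr__(self, "stimulus_azimuths", az)
        object.__setattr__(self, "stimulus_contrasts", c)
        if self.name not in self._KNOWN:
            raise InvalidParameterError(f"unknown treatment name {self.name!r}")
        if not 1 <= len(az) <= 2 or len(az) != len(c):
            raise InvalidParameterError(
                "treatments carry 1 or 2 stimuli with matching contrasts"
            )
        if any(not -1.0 <= x <= 0.0 for x in c):
            raise InvalidParameterError("contrasts must lie in [-1, 0]")
        if len(az) == 2:
            sep = abs(az[0] - az[1]) % 360.0
            sep = min(sep, 360.0 - sep)
            want = 90.0 if "90" in self.name else 180.0
            if abs(sep - want) > 1e-9:
                raise InvalidParameterError(
                    f"{self.name} requires {want:.0f} deg separation, got {sep}"
                )

    @property
    def paired(self) -> bool:
        return len(self.stimulus_azimuths) == 2


def experiment1_treatments() -> list[TreatmentSpec]:
    """Single / Paired 90 / Paired 180, all at -100% Weber contrast."""
    return [
        TreatmentSpec("Single", (0.0,), (-1.0,)),
        TreatmentSpec("Paired90", (0.0, 270.0), (-1.0, -1.0)),
        TreatmentSpec("Paired180", (0.0, 180.0), (-1.0, -1.0)),
    ]


def experiment2_treatments() -> list[TreatmentSpec]:
    """Contrast experiment: single LC / HC and mixed-contrast pairs."""
    return [
        TreatmentSpec("SingleLC", (0.0,), (-0.4,)),
        TreatmentSpec("SingleHC", (0.0,), (-1.0,)),
        TreatmentSpec("PairedContrast90", (0.0, 270.0), (-1.0, -0.4)),
        TreatmentSpec("PairedContrast180", (0.0, 180.0), (-1.0, -0.4)),
    ]


# ---------------------------------------------------------------------------
# Latin squares


def gen_latin_square(
    n_treatments: int, n_subjects: int, seed: int | None = None
) -> np.ndarray:
    """Randomized treatment-order matrix, subjects x serial position.

    Based on a cyclic Latin square with independently shuffled rows,
    columns and symbols; each subject (row) sees every treatment exactly
    once, and over any block of ``n_treatments`` subjects each treatment
    appears equally often at each serial position.  When ``n_subjects``
    is not a multiple of ``n_treatments`` the rows cycle, so positional
    balance holds approximately for the remainder.
    """
    if n_treatments < 2:
        raise InvalidParameterError("need at least 2 treatments")
    if n_subjects < 1:
        raise InvalidParameterError("need at least 1 subject")
    rng = np.random.default_rng(seed)
    n = n_treatments
    base = (np.arange(n)[:, None] + np.arange(n)[None, :]) % n
    square = base[rng.permutation(n)][:, rng.permutation(n)]
    square = rng.permutation(n)[square]
    rows = np.resize(np.arange(n_subjects) % n, n_subjects)
    return square[rows]


# ---------------------------------------------------------------------------
# behaviour


@dataclass(frozen=True)
class BehaviorGenParams:
    """Knobs of the behavioural generator.

    ``response_prob_by_treatment`` and ``timing_mean_sqrt`` accept either
    a scalar (shared by all treatments) or a mapping from treatment name.
    ``lateral_bias_strength`` weights stimulus choice by the axial
    alignment ``cos(2 * (stimulus azimuth - lateral body axis))``, so a
    laterally aligned stimulus (where crab acuity peaks) is
    preferentially escaped from; ``contrast_bias_strength`` weights by
    ``|Weber contrast|``.
    Timing is simulated on the square-root time-to-collision scale
    (sqrt-seconds), the scale on which escape timing is analysed.
    """

    response_prob_by_treatment: float | dict = 0.754
    kappa: float = 8.0
    attention_mode: str = "selective"  # selective | divided | mixed
    divided_fraction: float = 0.0
    lateral_bias_strength: float = 2.0
    contrast_bias_strength: float = 3.0
    timing_mean_sqrt: float | dict = 1.6
    timing_sd_sqrt: float = 0.25
    crab_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise InvalidParameterError("kappa must be > 0")
        if not 0.0 <= self.divided_fraction <= 1.0:
            raise InvalidParameterError("divided_fraction is a probability")
        if self.timing_sd_sqrt < 0 or self.crab_sd < 0:
            raise InvalidParameterError("SDs must be >= 0")
        if self.attention_mode not in ("selective", "divided", "mixed"):
            raise InvalidParameterError(
                f"unknown attention_mode {self.attention_mode!r}"
            )

    def response_prob(self, treatment: str) -> float:
        p = self.response_prob_by_treatment
        p = p.get(treatment, 0.754) if isinstance(p, dict) else float(p)
        if not 0.0 <= p <= 1.0:
            raise InvalidParameterError("response probability not in [0, 1]")
        return p

    def timing_mean(self, treatment: str) -> float:
        m = self.timing_mean_sqrt
        return m.get(treatment, 1.6) if isinstance(m, dict) else float(m)


def divided_modes(treatment: TreatmentSpec) -> list[float]:
    """Escape mode(s) maximising distance from all stimuli of a treatment.

    The circular mean of the away-directions; for opposed stimuli
    (180-deg separation) the mean is undefined and the two orthogonal
    directions are both solutions.
    """
    away = [(a + 180.0) % 360.0 for a in treatment.stimulus_azimuths]
    if len(away) == 1:
        return away
    summary = circ_summary(np.asarray(away))
    if summary.mean_defined:
        return [summary.mean_direction]
    return [
        (treatment.stimulus_azimuths[0] + 90.0) % 360.0,
        (treatment.stimulus_azimuths[0] + 270.0) % 360.0,
    ]


TRIAL_COLUMNS = [
    "crab_id",
    "sex",
    "treatment",
    "order",
    "stim_azimuth_1",
    "stim_azimuth_2",
    "contrast_1",
    "contrast_2",
    "body_orientation_deg",
    "responded",
    "time_to_collision_s",
    "escape_direction_deg",
]


def gen_escape_trials(
    params: BehaviorGenParams,
    treatments: list[TreatmentSpec],
    n_crabs: int,
    trials_per_crab: int = 1,
) -> pd.DataFrame:
    """Simulate a behavioural trial table.

    Each crab completes ``trials_per_crab`` full blocks in which it sees
    every treatment once, in a randomized Latin-square order.  Returns a
    tidy table (one row per trial); non-responding trials carry NaN
    timing and direction.  Fully reproducible from ``params.seed``.
    """
    if not treatments:
        raise InvalidParameterError("empty treatment list")
    if n_crabs < 1:
        raise InvalidParameterError("need at least 1 crab")
    rng = np.random.default_rng(params.seed)
    n_t = len(treatments)
    crab_offsets = rng.normal(0.0, params.crab_sd, size=n_crabs)
    sexes = rng.permuted(
        np.resize(np.array(["F", "M"]), n_crabs)
    )
    rows: list[dict] = []
    for block in range(trials_per_crab):
        order = gen_latin_square(
            n_t, n_crabs, seed=int(rng.integers(2**31))
        ) if n_t >= 2 else np.zeros((n_crabs, 1), dtype=int)
        for crab in range(n_crabs):
            for pos in range(order.shape[1]):
                tr = treatments[int(order[crab, pos])]
                rows.append(
                    _gen_one_trial(
                        params,
                        tr,
                        rng,
                        crab_id=f"crab{crab:03d}",
                        sex=str(sexes[crab]),
                        crab_offset=float(crab_offsets[crab]),
                        serial=block * n_t + pos + 1,
                    )
                )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _gen_one_trial(
    params: BehaviorGenParams,
    treatment: TreatmentSpec,
    rng: np.random.Generator,
    crab_id: str,
    sex: str,
    crab_offset: float,
    serial: int,
) -> dict:
    az = treatment.stimulus_azimuths
    contrasts = treatment.stimulus_contrasts
    orient = float(rng.uniform(0.0, 360.0))
    responded = bool(rng.random() < params.response_prob(treatment.name))
    timing = direction = np.nan
    if responded:
        mode = params.attention_mode
        if mode == "mixed":
            mode = (
                "divided"
                if rng.random() < params.divided_fraction
                else "selective"
            )
        if mode == "selective":
            # axial alignment of each stimulus with the lateral body axis:
            # cos(2*delta) is 1 on-axis, -1 perpendicular, 0 at 45 deg
            logw = np.array(
                [
                    params.lateral_bias_strength
                    * np.cos(2.0 * np.radians(a - orient))
                    + params.contrast_bias_strength * abs(c)
                    for a, c in zip(az, contrasts)
                ]
            )
            w = np.exp(logw - logw.max())
            chosen = int(rng.choice(len(az), p=w / w.sum()))
            target = (az[chosen] + 180.0) % 360.0
        else:
            modes = divided_modes(treatment)
            target = modes[int(rng.integers(len(modes)))]
        direction = float(
            np.degrees(rng.vonmises(np.radians(target), params.kappa)) % 360.0
        )
        sqrt_t = rng.normal(
            params.timing_mean(treatment.name) + crab_offset,
            params.timing_sd_sqrt,
        )
        timing = float(max(sqrt_t, 0.0) ** 2)
    return {
        "crab_id": crab_id,
        "sex": sex,
        "treatment": treatment.name,
        "order": serial,
        "stim_azimuth_1": az[0],
        "stim_azimuth_2": az[1] if len(az) == 2 else np.nan,
        "contrast_1": contrasts[0],
        "contrast_2": contrasts[1] if len(az) == 2 else np.nan,
        "body_orientation_deg": orient,
        "responded": int(responded),
        "time_to_collision_s": timing,
        "escape_direction_deg": direction,
    }


# ---------------------------------------------------------------------------
# spikes


@dataclass(frozen=True)
class SpikeGenParams:
    """Knobs of the inhomogeneous-Poisson spike generator.

    The instantaneous rate is

    ``lambda(t) = spont_rate + gain * contrast_scaling
                  * rule({w_i * |c_i| * expansion_rate_i(t)})``

    with receptive weights ``w_i`` (first stimulus = primary, second =
    secondary; equal weights emulate a uniform receptive field) and
    ``rule`` one of max / sum / average.  ``contrast_scaling`` is a
    global drive multiplier used to emulate contrast manipulations.
    """

    spont_rate: float = 2.0
    gain: float = 0.9  # Hz per (deg/s)
    integration_rule: str = "max"
    contrast_scaling: float = 1.0
    receptive_weight_primary: float = 1.0
    receptive_weight_secondary: float = 0.5
    trial_span: float | None = None  # s before collision; None -> full approach
    spont_span: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spont_rate < 0 or self.gain < 0:
            raise InvalidParameterError("rates and gain must be >= 0")
        if self.trial_span is not None and self.trial_span <= 0:
            raise InvalidParameterError("trial_span must be > 0")
        if self.spont_span <= 0:
            raise InvalidParameterError("spont_span must be > 0")
        if self.integration_rule not in ("max", "sum", "average"):
            raise InvalidParameterError(
                f"unknown integration rule {self.integration_rule!r}"
            )

    def weights(self, n_stimuli: int) -> np.ndarray:
        return np.array(
            [self.receptive_weight_primary, self.receptive_weight_secondary][
                :n_stimuli
            ]
        )


_RULES = {
    "max": lambda d: d.max(axis=0),
    "sum": lambda d: d.sum(axis=0),
    "average": lambda d: d.mean(axis=0),
}


def rate_function(
    stimuli: list[LoomingStimulus], params: SpikeGenParams
):
    """Return ``lambda(t)`` (Hz, t in s relative to collision) as a callable."""
    if not stimuli:
        raise InvalidParameterError("need at least one stimulus")
    weights = params.weights(len(stimuli))
    combine = _RULES[params.integration_rule]

    def lam(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        tau = np.clip(-t, 1e-9, None)
        drives = np.stack(
            [
                w * abs(s.weber_contrast) * expansion_rate(s, tau)
                for s, w in zip(stimuli, weights)
            ]
        )
        return (
            params.spont_rate
            + params.gain * params.contrast_scaling * combine(drives)
        )

    return lam


def gen_spike_train(
    stimuli: list[LoomingStimulus],
    params: SpikeGenParams,
    seed: int | None = None,
    **train_kwargs,
):
    """Simulate one spike train by Lewis thinning.

    The stimulated window runs from ``-trial_span`` (default: the full
    approach, i.e. the collision time of the first stimulus) to the
    predicted collision at 0; a homogeneous spontaneous segment of
    ``spont_span`` seconds precedes it.  Reproducible from the seed
    (``params.seed`` unless overridden).
    """
    from .spikes import SpikeTrain  # local import to avoid a cycle

    lam = rate_function(stimuli, params)
    span = params.trial_span or collision_time(stimuli[0])
    rng = np.random.default_rng(params.seed if seed is None else seed)
    grid = np.linspace(-span, -1e-6, 2048)
    lam_max = float(lam(grid).max()) * 1.0000001
    if lam_max > 0:
        n_cand = rng.poisson(lam_max * span)
        cand = rng.uniform(-span, 0.0, size=n_cand)
        keep = rng.uniform(0.0, lam_max, size=n_cand) < lam(cand)
        driven = cand[keep]
    else:
        driven = np.empty(0)
    n_spont = rng.poisson(params.spont_rate * params.spont_span)
    spont = rng.uniform(-span - params.spont_span, -span, size=n_spont)
    return SpikeTrain(
        spike_times=np.concatenate([spont, driven]),
        trial_span=(-span, 0.0),
        spont_span=(-span - params.spont_span, -span),
        **train_kwargs,
    )


EPHYS_STIMULUS = dict(
    object_diameter=30.0, approach_speed=90.0, start_distance=1000.0
)


def ephys_treatment_stimuli(
    contrast_primary: float = -1.0, contrast_secondary: float = -1.0
) -> dict[str, list[LoomingStimulus]]:
    """Stimulus sets for the three electrophysiology treatments.

    Primary and Secondary are single stimuli on the two monitors (90 deg
    apart); Paired presents both simultaneously.
    """
    primary = LoomingStimulus(
        azimuth=0.0, weber_contrast=contrast_primary, **EPHYS_STIMULUS
    )
    secondary = LoomingStimulus(
        azimuth=270.0, weber_contrast=contrast_secondary, **EPHYS_STIMULUS
    )
    return {
        "Primary": [primary],
        "Secondary": [secondary],
        "Paired": [primary, secondary],
    }


def gen_ephys_population(
    params: SpikeGenParams,
    n_neurons: int = 20,
    trials_per_treatment: int = 3,
    weight_jitter: float = 0.1,
    gain_jitter: float = 0.2,
    contrasts: tuple[float, float] = (-1.0, -1.0),
    seed: int | None = None,
) -> list:
    """Spike trains for a synthetic population of looming-sensitive neurons.

    Each neuron gets its own receptive weights and gain (lognormal jitter
    around the population parameters, emulating receptive-field
    inhomogeneity across cells) and is recorded under the Primary /
    Secondary / Paired treatments.  Returns a flat list of SpikeTrain.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    stimuli = ephys_treatment_stimuli(*contrasts)
    trains = []
    for j in range(n_neurons):
        cell = replace(
            params,
            gain=params.gain * float(rng.lognormal(0.0, gain_jitter)),
            receptive_weight_primary=params.receptive_weight_primary
            * float(rng.lognormal(0.0, weight_jitter)),
            receptive_weight_secondary=params.receptive_weight_secondary
            * float(rng.lognormal(0.0, weight_jitter)),
        )
        for treatment, stims in stimuli.items():
            if treatment == "Secondary":
                # the lone stimulus sits at the secondary location
                cell_t = replace(
                    cell,
                    receptive_weight_primary=cell.receptive_weight_secondary,
                )
            else:
                cell_t = cell
            for k in range(trials_per_treatment):
                trains.append(
                    gen_spike_train(
                        stims,
                        cell_t,
                        seed=int(rng.integers(2**31)),
                        neuron_id=f"neuron{j:03d}",
                        crab_id=f"crab{j // 2:03d}",
                        trial_id=f"n{j:03d}_{treatment}_{k}",
                        treatment=treatment,
                    )
                )
    return trains
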