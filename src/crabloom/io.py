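"""File formats, configuration and report serialization.

Everything is plain delimited text + YAML + JSON: the experiments are
small (tens of crabs, tens of neurons) and gain nothing from binary
electrophysiology containers.  Angles are stored in degrees, times in
seconds relative to predicted collision.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attention import AnalysisConfig
from .circstats import InvalidInputError
from .spikes import SpikeTrain
from .synth import (
    BehaviorGenParams,
    SpikeGenParams,
    TreatmentSpec,
    experiment1_treatments,
)

logger = logging.getLogger("crabloom")


class SchemaError(ValueError):
    """A data file is missing required structure."""


TRIAL_REQUIRED = [
    "crab_id",
    "sex",
    "treatment",
    "stim_azimuth_1",
    "stim_azimuth_2",
    "contrast_1",
    "contrast_2",
    "body_orientation_deg",
    "responded",
    "time_to_collision_s",
    "escape_direction_deg",
]

SPIKE_COLUMNS = ["neuron_id", "crab_id", "trial_id", "treatment", "spike_time_s"]
SPIKE_META_COLUMNS = [
    "trial_id",
    "neuron_id",
    "crab_id",
    "treatment",
    "trial_start_s",
    "trial_end_s",
    "spont_start_s",
    "spont_end_s",
]


# ---------------------------------------------------------------------------
# trial tables


def write_trials(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a behavioural trial table (CSV).

    Raises :class:`SchemaError` naming any missing required column, and
    a row-level error (with 1-based data line number) for responding
    trials without an escape direction or for angles outside [0, 360)
    that cannot be normalized.  Angles are normalized to [0, 360).
    """
    table = pd.read_csv(path)
    missing = [c for c in TRIAL_REQUIRED if c not in table.columns]
    if missing:
        raise SchemaError(f"trial table missing required column(s): {missing}")
    for col in ("body_orientation_deg", "escape_direction_deg",
                "stim_azimuth_1", "stim_azimuth_2"):
        table[col] = np.mod(table[col].astype(float), 360.0)
    responded = table["responded"].astype(float).fillna(0).astype(int)
    bad = responded.eq(1) & table["escape_direction_deg"].isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise InvalidInputError(
            f"row at line {line}: responded=1 but escape direction missing"
        )
    table["responded"] = responded
    logger.info("read %d trials from %s", len(table), path)
    return table


# ---------------------------------------------------------------------------
# spike trains


def write_spikes(trains: list[SpikeTrain], spikes_path, meta_path) -> None:
    """Write spike trains as long-format events plus a trial metadata table."""
    events, meta = [], []
    for tr in trains:
        meta.append(
            {
                "trial_id": tr.trial_id,
                "neuron_id": tr.neuron_id,
                "crab_id": tr.crab_id,
                "treatment": tr.treatment,
                "trial_start_s": tr.trial_span[0],
                "trial_end_s": tr.trial_span[1],
                "spont_start_s": tr.spont_span[0] if tr.spont_span else np.nan,
                "spont_end_s": tr.spont_span[1] if tr.spont_span else np.nan,
            }
        )
        for t in tr.spike_times:
            events.append(
                {
                    "neuron_id": tr.neuron_id,
                    "crab_id": tr.crab_id,
                    "trial_id": tr.trial_id,
                    "treatment": tr.treatment,
                    "spike_time_s": t,
                }
            )
    pd.DataFrame(events, columns=SPIKE_COLUMNS).to_csv(spikes_path, index=False)
    pd.DataFrame(meta, columns=SPIKE_META_COLUMNS).to_csv(meta_path, index=False)


def read_spikes(spikes_path, meta_path) -> list[SpikeTrain]:
    """Read per-trial spike trains; times are sorted, spans validated."""
    events = pd.read_csv(spikes_path)
    meta = pd.read_csv(meta_path)
    for frame, cols, name in (
        (events, SPIKE_COLUMNS, "spike table"),
        (meta, SPIKE_META_COLUMNS, "spike metadata table"),
    ):
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise SchemaError(f"{name} missing required column(s): {missing}")
    by_trial = dict(tuple(events.groupby("trial_id", sort=False)))
    trains = []
    for row in meta.itertuples(index=False):
        ev = by_trial.get(row.trial_id)
        times = (
            np.sort(ev["spike_time_s"].to_numpy(float))
            if ev is not None
            else np.empty(0)
        )
        spont = (
            None
            if pd.isna(row.spont_start_s)
            else (float(row.spont_start_s), float(row.spont_end_s))
        )
        trains.append(
            SpikeTrain(
                spike_times=times,
                trial_span=(float(row.trial_start_s), float(row.trial_end_s)),
                spont_span=spont,
                neuron_id=str(row.neuron_id),
                crab_id=str(row.crab_id),
                trial_id=str(row.trial_id),
                treatment=str(row.treatment),
            )
        )
    logger.info(
        "read %d spike trains (%d events) from %s",
        len(trains),
        len(events),
        spikes_path,
    )
    return trains


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Seed, treatments, generator parameters and analysis thresholds."""

    seed: int = 0
    treatments: list[TreatmentSpec] = field(
        default_factory=experiment1_treatments
    )
    behavior: BehaviorGenParams = field(default_factory=BehaviorGenParams)
    spikes: SpikeGenParams = field(default_factory=SpikeGenParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    n_crabs: int = 50
    trials_per_crab: int = 1
    n_neurons: int = 20
    outdir: str = "."

    def to_dict(self) -> dict:
        d = asdict(self)
        d["treatments"] = [asdict(t) for t in self.treatments]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "treatments" in d:
            d["treatments"] = [
                TreatmentSpec(
                    name=t["name"],
                    stimulus_azimuths=tuple(t["stimulus_azimuths"]),
                    stimulus_contrasts=tuple(t["stimulus_contrasts"]),
                )
                for t in d["treatments"]
            ]
        for key, typ in (
            ("behavior", BehaviorGenParams),
            ("spikes", SpikeGenParams),
            ("analysis", AnalysisConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    def with_seed(self, seed: int) -> "RunConfig":
        from dataclasses import replace

        return replace(
            self,
            seed=seed,
            behavior=BehaviorGenParams(
                **{**asdict(self.behavior), "seed": seed}
            ),
            spikes=SpikeGenParams(**{**asdict(self.spikes), "seed": seed + 1}),
            analysis=AnalysisConfig(
                **{**asdict(self.analysis), "seed": seed + 2}
            ),
        )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# reports


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_report(report: dict, path, config: RunConfig | None = None) -> None:
    """Write an analysis report as deterministic, provenance-stamped JSON."""
    payload = {
        "provenance": {
            "package": "crabloom",
            "version": __version__,
            "seed": config.seed if config else None,
            "config_sha256": config_hash(config) if config else None,
        },
        "report": _jsonable(report),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
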