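"""Delimited-text formats, config files and run manifests.

Every writer/reader pair is a round trip: writing an object and reading it
back reproduces it exactly (floats are written with 17 significant digits
and parsed with correctly-rounded conversion).  Schema violations are reported with the offending field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assessment import TrialSequence
from .cohort import CohortSpec
from .eegsim import EEGRecording, EvokedSimSpec
from .engine import GameConfig, GameRecord, TrainingLog
from .erp import EpochSet

TRAINING_LOG_COLUMNS = [
    "participant_id", "game_index", "level", "mean_rt_ms",
    "n_correct_go", "n_correct_nogo", "n_errors", "n_omissions", "timestamp",
]


class SchemaError(ValueError):
    """A file does not match its expected schema."""


def _require_columns(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


# ---------------------------------------------------------------------------
# training logs

def training_logs_frame(logs) -> pd.DataFrame:
    rows = []
    for log in logs:
        for rec in log.records:
            day = (rec.game_index - 1) // log.games_per_day + 1
            rows.append(
                {
                    "participant_id": log.participant_id,
                    "game_index": rec.game_index,
                    "level": rec.level,
                    "mean_rt_ms": rec.mean_rt_ms,
                    "n_correct_go": rec.n_correct_go,
                    "n_correct_nogo": rec.n_correct_nogo,
                    "n_errors": rec.n_errors,
                    "n_omissions": rec.n_omissions,
                    "timestamp": f"day{day:02d}",
                }
            )
    return pd.DataFrame(rows, columns=TRAINING_LOG_COLUMNS)


def write_training_logs(logs, path) -> None:
    training_logs_frame(logs).to_csv(path, index=False, float_format="%.17g")


def read_training_logs(path) -> list[TrainingLog]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRAINING_LOG_COLUMNS[:-1], "training log")
    logs = []
    for pid, sub in df.groupby("participant_id", sort=False):
        sub = sub.sort_values("game_index")
        if not (sub["game_index"].diff().dropna() > 0).all():
            raise SchemaError(f"training log: game_index not increasing for {pid}")
        records = [
            GameRecord(
                game_index=int(r.game_index),
                level=int(r.level),
                mean_rt_ms=float(r.mean_rt_ms),
                n_correct_go=int(r.n_correct_go),
                n_correct_nogo=int(r.n_correct_nogo),
                n_errors=int(r.n_errors),
                n_omissions=int(r.n_omissions),
            )
            for r in sub.itertuples()
        ]
        logs.append(TrainingLog(participant_id=str(pid), records=records))
    return logs


# ---------------------------------------------------------------------------
# assessment event markers

def write_events(sequences, path) -> None:
    """Event marker file: onset_ms, label, task — consumed by the ERP stage."""
    pd.concat([s.to_frame() for s in sequences], ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_events(path) -> list[TrialSequence]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["onset_ms", "label", "task"], "events")
    out = []
    for task, sub in df.groupby("task", sort=False):
        onsets = sub["onset_ms"].to_numpy(dtype=float)
        spacing = np.diff(onsets)
        if len(spacing) and not (spacing > 0).all():
            raise SchemaError("events: onsets must be strictly increasing")
        isi = float(spacing[0]) if len(spacing) else 0.0
        out.append(
            TrialSequence(
                labels=tuple(sub["label"].tolist()),
                onsets_ms=tuple(onsets.tolist()),
                isi_ms=isi,
                variant=str(task),
            )
        )
    return out


# ---------------------------------------------------------------------------
# continuous EEG (delimited matrix + JSON header + events file)

def write_eeg(rec: EEGRecording, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = {"ch_names": list(rec.ch_names), "sfreq_hz": rec.sfreq_hz}
    (directory / "header.json").write_text(json.dumps(header, indent=1))
    pd.DataFrame(rec.data_uv.T, columns=list(rec.ch_names)).to_csv(
        directory / "data.csv", index=False, float_format="%.17g"
    )
    pd.DataFrame(rec.events, columns=["sample", "label"]).to_csv(
        directory / "events.csv", index=False
    )


def read_eeg(directory) -> EEGRecording:
    directory = Path(directory)
    header = json.loads((directory / "header.json").read_text())
    for key in ("ch_names", "sfreq_hz"):
        if key not in header:
            raise SchemaError(f"EEG header: missing field {key!r}")
    data = pd.read_csv(directory / "data.csv", float_precision="round_trip")
    if list(data.columns) != list(header["ch_names"]):
        raise SchemaError("EEG data: channel columns do not match the header")
    ev = pd.read_csv(directory / "events.csv")
    _require_columns(ev, ["sample", "label"], "EEG events")
    return EEGRecording(
        data_uv=data.to_numpy(dtype=float).T,
        sfreq_hz=float(header["sfreq_hz"]),
        ch_names=tuple(header["ch_names"]),
        events=[(int(s), str(l)) for s, l in zip(ev["sample"], ev["label"])],
    )


# ---------------------------------------------------------------------------
# epoch arrays (runtime .npy + JSON index sidecar)

def write_epochs(epochs: EpochSet, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "epochs.npy", epochs.data_uv)
    index = {
        "times_ms": epochs.times_ms.tolist(),
        "ch_names": list(epochs.ch_names),
        "labels": [str(l) for l in epochs.labels],
        "sfreq_hz": epochs.sfreq_hz,
        "accepted": epochs.accepted.astype(bool).tolist(),
        "reject_reason": [str(r) for r in epochs.reject_reason],
    }
    (directory / "index.json").write_text(json.dumps(index))


def read_epochs(directory) -> EpochSet:
    directory = Path(directory)
    index = json.loads((directory / "index.json").read_text())
    for key in ("times_ms", "ch_names", "labels", "sfreq_hz", "accepted"):
        if key not in index:
            raise SchemaError(f"epoch index: missing field {key!r}")
    return EpochSet(
        data_uv=np.load(directory / "epochs.npy"),
        times_ms=np.array(index["times_ms"], dtype=float),
        ch_names=tuple(index["ch_names"]),
        labels=np.array(index["labels"], dtype=object),
        sfreq_hz=float(index["sfreq_hz"]),
        accepted=np.array(index["accepted"], dtype=bool),
        reject_reason=np.array(index["reject_reason"], dtype=object),
    )


# ---------------------------------------------------------------------------
# cohort and ANOVA tables

def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.17g")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["participant_id", "condition", "time"], "cohort table")
    return df


def write_anova_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration and manifest

@dataclass(frozen=True)
class RunConfig:
    """Umbrella configuration of one end-to-end simulated study run."""

    seed: int = 0
    out_dir: str = "ictrain-run"
    game: GameConfig = field(default_factory=GameConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    evoked: EvokedSimSpec = field(default_factory=EvokedSimSpec)
    n_games_target: int = 140
    adherence_cutoff: int = 90
    n_sessions: int = 3
    dropout_prop: float = 0.15
    eeg_n_per_condition: int = 6
    assessment_n_trials: int = 100

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required for stochastic stages")


_SUBCONFIGS = {"game": GameConfig, "cohort": CohortSpec, "evoked": EvokedSimSpec}


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file of (possibly partial) overrides."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, value in raw.items():
        if key in _SUBCONFIGS:
            kwargs[key] = _SUBCONFIGS[key](**value)
        else:
            kwargs[key] = value
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise SchemaError(f"run config: {exc}") from None


def config_digest(config: RunConfig) -> str:
    def encode(obj):
        if dataclasses.is_dataclass(obj):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): encode(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        return obj

    canonical = json.dumps(encode(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def write_manifest(config: RunConfig, path) -> None:
    """Enough metadata to re-execute a run bit-identically."""
    import scipy

    from . import __version__

    manifest = {
        "config_sha256": config_digest(config),
        "seed": config.seed,
        "versions": {
            "ictrain": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=1))
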