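"""Serialization: HDF5 epochs container, traits CSV, results CSV, null JSON.

The epochs container is one HDF5 file (datasets ``/data``, ``/labels``,
``/set_tag``) plus a JSON sidecar carrying the sensor layout, sampling
metadata, subject id and an optional configuration echo.  All tabular outputs
are comma-separated UTF-8 with a mandatory header row and "." decimals.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .association import AssociationResult, associations_to_frame
from .decoding import DecodingResult
from .significance import NullModel
from .synthetic import ChannelInfo, EpochsSet, SensorLayout, TraitProfile

__all__ = [
    "write_epochs",
    "read_epochs",
    "layout_to_dict",
    "layout_from_dict",
    "write_traits_csv",
    "read_traits_csv",
    "results_to_frame",
    "write_results_csv",
    "read_results_csv",
    "write_null_json",
    "read_null_json",
    "to_mne_epochs",
    "export_fif",
]

TRAIT_COLUMNS = ["subject_id", "EC", "PT", "FS", "PD", "ani_EC", "ani_PT"]


# -- sensor layout ----------------------------------------------------------


def layout_to_dict(layout: SensorLayout) -> list[dict]:
    return [
        {"name": c.name, "modality": c.modality, "pair_id": c.pair_id, "group": c.group}
        for c in layout.channels
    ]


def layout_from_dict(channels: list[dict]) -> SensorLayout:
    return SensorLayout(
        channels=tuple(
            ChannelInfo(c["name"], c["modality"], c["pair_id"], c["group"])
            for c in channels
        )
    )


# -- epochs container -------------------------------------------------------


def _sidecar_path(h5_path: Path) -> Path:
    return h5_path.with_suffix(h5_path.suffix + ".json")


def write_epochs(
    epochs: EpochsSet,
    h5_path: str | Path,
    sidecar_path: str | Path | None = None,
    extra_meta: dict | None = None,
) -> tuple[Path, Path]:
    """Write the trial tensor to HDF5 and the metadata to a JSON sidecar."""
    h5_path = Path(h5_path)
    sidecar = Path(sidecar_path) if sidecar_path else _sidecar_path(h5_path)
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset(
            "labels", data=np.array([str(x) for x in epochs.labels], dtype="S")
        )
        f.create_dataset(
            "set_tag", data=np.array([str(x) for x in epochs.set_tag], dtype="S")
        )
    meta = {
        "subject_id": epochs.subject_id,
        "sampling_rate": epochs.sampling_rate,
        "t0_offset": epochs.t0_offset,
        "layout": layout_to_dict(epochs.layout),
    }
    if extra_meta:
        meta["extra"] = extra_meta
    sidecar.write_text(json.dumps(meta, indent=1))
    return h5_path, sidecar


def read_epochs(h5_path: str | Path, sidecar_path: str | Path | None = None) -> EpochsSet:
    h5_path = Path(h5_path)
    sidecar = Path(sidecar_path) if sidecar_path else _sidecar_path(h5_path)
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed sidecar {sidecar}: {e}") from e
    for key in ("subject_id", "sampling_rate", "t0_offset", "layout"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} lacks required field {key!r}")
    with h5py.File(h5_path, "r") as f:
        data = f["data"][()]
        labels = np.array([s.decode() for s in f["labels"][()]], dtype=object)
        set_tag = np.array([s.decode() for s in f["set_tag"][()]], dtype=object)
    return EpochsSet(
        subject_id=meta["subject_id"],
        data=data,
        labels=labels,
        set_tag=set_tag,
        layout=layout_from_dict(meta["layout"]),
        sampling_rate=float(meta["sampling_rate"]),
        t0_offset=float(meta["t0_offset"]),
    )


# -- traits -----------------------------------------------------------------


def write_traits_csv(profiles: Sequence[TraitProfile], path: str | Path) -> Path:
    rows = [
        {col: getattr(p, col) if col != "subject_id" else p.subject_id for col in TRAIT_COLUMNS}
        for p in profiles
    ]
    pd.DataFrame(rows, columns=TRAIT_COLUMNS).to_csv(path, index=False)
    return Path(path)


def read_traits_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"traits CSV {path} lacks required column(s) {missing}")
    return df


# -- decoding results -------------------------------------------------------


def results_to_frame(results: Sequence[DecodingResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        static = r.window == "static"
        rows.append(
            {
                "subject_id": r.subject_id,
                "modality": r.config.get("modality"),
                "pair": "-".join(r.pair),
                "window_start_ms": None if static else r.window[0],
                "window_end_ms": None if static else r.window[1],
                "mode": "static" if static else "timewise",
                "accuracy": r.accuracy,
                "fold_accuracies": json.dumps(r.fold_accuracies),
                "n_features": r.n_features,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)


def write_results_csv(results: Sequence[DecodingResult] | pd.DataFrame, path: str | Path) -> Path:
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    df.to_csv(path, index=False)
    return Path(path)


def read_results_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "pair", "mode", "accuracy"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"results CSV {path} lacks required column(s) {missing}")
    if "fold_accuracies" in df.columns:
        df["fold_accuracies"] = df["fold_accuracies"].map(
            lambda s: json.loads(s) if isinstance(s, str) else s
        )
    return df


# -- null model -------------------------------------------------------------


def write_null_json(null: NullModel, path: str | Path) -> Path:
    payload = {
        "n_permutations": null.n_permutations,
        "alpha": null.alpha,
        "threshold": null.threshold,
        "max_statistics": null.max_statistics.tolist(),
        "config": {
            k: (list(map(list, v)) if isinstance(v, tuple) else v)
            for k, v in null.config.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))
    return Path(path)


def read_null_json(path: str | Path) -> NullModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed null-model JSON {path}: {e}") from e
    cfg = payload["config"]
    if isinstance(cfg.get("windows"), list):
        cfg["windows"] = tuple(tuple(w) for w in cfg["windows"])
    return NullModel(
        n_permutations=payload["n_permutations"],
        max_statistics=np.asarray(payload["max_statistics"], dtype=float),
        alpha=payload["alpha"],
        threshold=payload["threshold"],
        config=cfg,
    )


# -- optional FIF export (feature-flagged: requires the 'fif' extra) --------


def to_mne_epochs(epochs: EpochsSet):
    """Convert to an mne.EpochsArray (requires the optional mne dependency)."""
    try:
        import mne
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ImportError(
            "FIF export requires mne; install the 'fif' extra"
        ) from e
    ch_types = [
        "grad" if c.modality == "planar_gradiometer" else "eeg"
        for c in epochs.layout.channels
    ]
    info = mne.create_info(epochs.layout.names, epochs.sampling_rate, ch_types)
    cats = epochs.categories()
    event_id = {c: i + 1 for i, c in enumerate(cats)}
    events = np.column_stack(
        [
            np.arange(epochs.n_trials),
            np.zeros(epochs.n_trials, dtype=int),
            [event_id[str(l)] for l in epochs.labels],
        ]
    )
    return mne.EpochsArray(
        epochs.data,
        info,
        events=events,
        tmin=epochs.t0_offset / 1000.0,
        event_id=event_id,
        verbose="error",
    )


def export_fif(epochs: EpochsSet, path: str | Path) -> Path:
    to_mne_epochs(epochs).save(str(path), overwrite=True, verbose="error")
    return Path(path)


def write_associations_csv(
    results: Sequence[AssociationResult] | pd.DataFrame, path: str | Path
) -> Path:
    df = results if isinstance(results, pd.DataFrame) else associations_to_frame(results)
    df.to_csv(path, index=False)
    return Path(path)
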