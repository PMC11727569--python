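"""Reading and writing recordings, windowed datasets and checkpoints.

Three recording formats are supported:

``csv``
    One row per sample, header required: ``ch1..chT,label,repetition``.
    Sampling rate and subject id travel in a JSON sidecar (``<file>.json``)
    or are passed explicitly.
``npz``
    Binary array container (``signal``, ``labels``, ``repetitions``) with
    the same JSON sidecar.
``mat``
    The conventional benchmark layout: variables ``emg``,
    ``stimulus``/``restimulus`` and ``repetition``/``rerepetition``; the
    refined (``re``-prefixed) variables are preferred when present.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.io import loadmat, savemat

from .network import ModelConfig
from .preprocessing import ChannelStats, RawRecording, WindowedDataset

logger = logging.getLogger(__name__)

__all__ = [
    "read_recording", "write_recording",
    "read_recording_csv", "write_recording_csv",
    "read_recording_npz", "write_recording_npz",
    "read_recording_mat", "write_recording_mat",
    "save_windows", "load_windows",
    "save_checkpoint", "load_checkpoint",
]

FORMATS = ("csv", "npz", "mat")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path, f: float, subject_id: str) -> None:
    _sidecar_path(path).write_text(json.dumps({"f": f, "subject_id": subject_id}))


def _read_sidecar(path: Path) -> Dict:
    sc = _sidecar_path(path)
    if sc.exists():
        return json.loads(sc.read_text())
    return {}


# -- CSV ------------------------------------------------------------------

def write_recording_csv(rec: RawRecording, path) -> None:
    path = Path(path)
    cols = {f"ch{i + 1}": rec.signal[:, i] for i in range(rec.n_channels)}
    cols["label"] = rec.labels
    cols["repetition"] = rec.repetitions
    pd.DataFrame(cols).to_csv(path, index=False)
    _write_sidecar(path, rec.f, rec.subject_id)


def read_recording_csv(path, f: Optional[float] = None,
                       subject_id: Optional[str] = None) -> RawRecording:
    path = Path(path)
    meta = _read_sidecar(path)
    f = f if f is not None else meta.get("f")
    if f is None:
        raise ValueError(f"sampling frequency unknown: pass f= or provide {_sidecar_path(path).name}")
    subject_id = subject_id or meta.get("subject_id", path.stem)
    df = pd.read_csv(path)
    for col in ("label", "repetition"):
        if col not in df.columns:
            raise ValueError(f"CSV {path} is missing the required column {col!r}")
    chan_cols = [c for c in df.columns if c.startswith("ch")]
    if not chan_cols:
        raise ValueError(f"CSV {path} has no channel columns (ch1..chT)")
    chan_cols = sorted(chan_cols, key=lambda c: int(c[2:]))
    sig = df[chan_cols].to_numpy()
    if not np.issubdtype(sig.dtype, np.number):
        raise ValueError(f"CSV {path} contains non-numeric channel cells")
    return RawRecording(sig, float(f), df["label"].to_numpy(),
                        df["repetition"].to_numpy(), subject_id)


# -- NPZ array container --------------------------------------------------

def write_recording_npz(rec: RawRecording, path) -> None:
    path = Path(path)
    np.savez(path, signal=rec.signal, labels=rec.labels, repetitions=rec.repetitions)
    _write_sidecar(path, rec.f, rec.subject_id)


def read_recording_npz(path, f: Optional[float] = None,
                       subject_id: Optional[str] = None) -> RawRecording:
    path = Path(path)
    meta = _read_sidecar(path)
    f = f if f is not None else meta.get("f")
    if f is None:
        raise ValueError(f"sampling frequency unknown: pass f= or provide {_sidecar_path(path).name}")
    with np.load(path) as z:
        missing = {"signal", "labels", "repetitions"} - set(z.files)
        if missing:
            raise ValueError(f"array container {path} is missing {sorted(missing)}")
        return RawRecording(z["signal"], float(f), z["labels"], z["repetitions"],
                            subject_id or meta.get("subject_id", path.stem))


# -- MAT (benchmark variable layout) --------------------------------------

def write_recording_mat(rec: RawRecording, path, refined: bool = True) -> None:
    label_key = "restimulus" if refined else "stimulus"
    rep_key = "rerepetition" if refined else "repetition"
    savemat(str(path), {
        "emg": rec.signal,
        label_key: rec.labels.reshape(-1, 1),
        rep_key: rec.repetitions.reshape(-1, 1),
        "frequency": np.array([[rec.f]]),
        "subject": np.array([rec.subject_id], dtype=object),
    })


def read_recording_mat(path, f: Optional[float] = None,
                       subject_id: Optional[str] = None) -> RawRecording:
    path = Path(path)
    mat = loadmat(str(path))
    if "emg" not in mat:
        raise ValueError(f"MAT file {path} has no 'emg' variable")
    sig = np.asarray(mat["emg"], dtype=np.float64)

    if "restimulus" in mat:
        labels = mat["restimulus"]
    elif "stimulus" in mat:
        logger.info("MAT file %s has no 'restimulus'; falling back to 'stimulus'", path)
        labels = mat["stimulus"]
    else:
        raise ValueError(f"MAT file {path} has neither 'restimulus' nor 'stimulus'")

    if "rerepetition" in mat:
        reps = mat["rerepetition"]
    elif "repetition" in mat:
        logger.info("MAT file %s has no 'rerepetition'; falling back to 'repetition'", path)
        reps = mat["repetition"]
    else:
        raise ValueError(f"MAT file {path} has neither 'rerepetition' nor 'repetition'")

    if f is None:
        if "frequency" in mat:
            f = float(np.asarray(mat["frequency"]).ravel()[0])
        else:
            raise ValueError(f"sampling frequency unknown: MAT file {path} has no 'frequency'")
    if subject_id is None:
        if "subject" in mat:
            subject_id = str(np.asarray(mat["subject"]).ravel()[0])
        else:
            subject_id = path.stem
    return RawRecording(sig, f, np.asarray(labels).ravel(), np.asarray(reps).ravel(),
                        subject_id)


_READERS = {"csv": read_recording_csv, "npz": read_recording_npz, "mat": read_recording_mat}
_WRITERS = {"csv": write_recording_csv, "npz": write_recording_npz, "mat": write_recording_mat}


def read_recording(path, format: Optional[str] = None, **kwargs) -> RawRecording:
    """Dispatch on the declared format (or the file extension)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt not in _READERS:
        raise ValueError(f"unknown recording format {fmt!r}; expected one of {FORMATS}")
    return _READERS[fmt](path, **kwargs)


def write_recording(rec: RawRecording, path, format: Optional[str] = None, **kwargs) -> None:
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt not in _WRITERS:
        raise ValueError(f"unknown recording format {fmt!r}; expected one of {FORMATS}")
    _WRITERS[fmt](rec, path, **kwargs)


# -- windowed datasets ----------------------------------------------------

def save_windows(ds: WindowedDataset, path) -> None:
    path = Path(path)
    np.savez(path, images=ds.images, labels=ds.labels, repetitions=ds.repetitions)
    meta = {"w_ms": ds.w_ms, "s_ms": ds.s_ms, "f": ds.f, "subject_id": ds.subject_id}
    _sidecar_path(path).write_text(json.dumps(meta))


def load_windows(path) -> WindowedDataset:
    path = Path(path)
    meta = _read_sidecar(path)
    if not meta:
        raise ValueError(f"windowed dataset {path} is missing its JSON sidecar")
    with np.load(path) as z:
        return WindowedDataset(z["images"], z["labels"], z["repetitions"],
                               meta["w_ms"], meta["s_ms"], meta["f"],
                               meta.get("subject_id", "S?"))


# -- model checkpoints ----------------------------------------------------

def save_checkpoint(path, model, variant: str,
                    stats: Optional[ChannelStats] = None,
                    extra: Optional[Dict] = None) -> None:
    """Serialise model weights + config (+ normaliser stats) to one .npz."""
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    meta = {
        "variant": variant,
        "model_config": model.cfg.to_dict(),
        "n_state_arrays": len(arrays),
        "extra": extra or {},
    }
    if stats is not None:
        arrays["stats_mu"] = stats.mu
        arrays["stats_sigma"] = stats.sigma
    arrays["meta_json"] = np.array(json.dumps(meta))
    np.savez(Path(path), **arrays)


def load_checkpoint(path, n_channels: Optional[int] = None):
    """Rebuild (model, stats, meta) from a checkpoint written by
    :func:`save_checkpoint`. ``n_channels`` is needed only for the pure
    recurrent variant, whose input width is the electrode count."""
    from .training import build_ablation  # deferred: training imports network

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint {path} does not exist")
    with np.load(path) as z:
        meta = json.loads(str(z["meta_json"][()]))
        cfg = ModelConfig.from_dict(meta["model_config"])
        if n_channels is None:
            n_channels = int(meta.get("extra", {}).get("n_channels", 0)) or 8
        model = build_ablation(meta["variant"], cfg, n_channels)
        arrays = [z[f"arr_{i}"] for i in range(meta["n_state_arrays"])]
        model.load_state_arrays(arrays)
        model.eval()
        stats = None
        if "stats_mu" in z.files:
            stats = ChannelStats(z["stats_mu"], z["stats_sigma"])
    return model, stats, meta
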