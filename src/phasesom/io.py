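"""Reading and writing recordings, connectivity matrices and result tables.

Two on-disk recording formats are supported: EDF (read-only, via mne) and a
plain delimited channels x samples matrix accompanied by a JSON sidecar
holding the sampling rate, channel labels and subject metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .recording import Recording

_FLOAT_FMT = "%.12g"  # 12 significant digits so determinism checks are meaningful


def read_edf(path: str | Path, exclude: list[str] | None = None) -> Recording:
    """Load an EDF recording; all selected channels must share one rate."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such EDF file: {path}")
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error",
                              exclude=exclude or [])
    info = raw.info
    rates = {info["sfreq"]}
    if len(rates) != 1:
        raise ValueError(f"mixed sampling rates in {path}: unsupported layout")
    try:
        data = raw.get_data(units="uV")  # keep the recorded physical units
    except ValueError:
        data = raw.get_data()
    return Recording(
        data=data,
        fs=float(info["sfreq"]),
        channel_labels=list(raw.ch_names),
        subject_id=path.stem,
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_matrix(rec: Recording, path: str | Path, delimiter: str = "\t") -> None:
    """Write a recording as a delimited matrix plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, rec.data, fmt=_FLOAT_FMT, delimiter=delimiter)
    meta = {
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "subject_id": rec.subject_id,
        "group": rec.group,
        "stimulus": rec.stimulus,
        "edge_margin": rec.edge_margin,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_matrix(path: str | Path, sidecar: str | Path | None = None,
                delimiter: str = "\t") -> Recording:
    """Load a delimited matrix recording with its JSON sidecar."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such matrix file: {path}")
    sidecar = Path(sidecar) if sidecar else _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar for {path}: {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta:
        raise ValueError(f"sidecar {sidecar} lacks the sampling rate 'fs'")
    data = np.atleast_2d(np.loadtxt(path, delimiter=delimiter))
    labels = meta.get("channel_labels")
    if labels is None:
        labels = [f"ch{i:02d}" for i in range(data.shape[0])]
    if len(labels) != data.shape[0]:
        raise ValueError(
            f"{len(labels)} labels for {data.shape[0]} matrix rows in {path}"
        )
    return Recording(
        data=data,
        fs=float(meta["fs"]),
        channel_labels=list(labels),
        subject_id=meta.get("subject_id", path.stem),
        group=meta.get("group", "unknown"),
        stimulus=meta.get("stimulus", "none"),
        edge_margin=int(meta.get("edge_margin", 0)),
    )


def write_connectivity(cm: ConnectivityMatrix, path: str | Path) -> None:
    """Labeled CSV of the matrix plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(cm.values, index=cm.channel_labels, columns=cm.channel_labels)
    df.to_csv(path, float_format=_FLOAT_FMT)
    meta = {
        "method": cm.method,
        "band": cm.band.name if cm.band else None,
        "n_samples": cm.n_samples,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_connectivity_values(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
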