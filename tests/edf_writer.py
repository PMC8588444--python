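"""Minimal EDF writer for test fixtures (synthetic recordings only).

Writes a plain EDF file (one data record per second, 16-bit samples) just
rich enough for standards-compliant readers; not a general-purpose exporter.
"""

from __future__ import annotations

import numpy as np


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field too long: {text!r}")
    return b + b" " * (width - len(b))


def write_edf(path, data: np.ndarray, fs: float, labels: list[str]) -> None:
    data = np.asarray(data, dtype=float)
    ns, n_samples = data.shape
    spr = int(round(fs))  # samples per 1 s record
    if fs != spr:
        raise ValueError("integer sampling rates only in this fixture writer")
    n_records = n_samples // spr
    if n_records < 1:
        raise ValueError("need at least one full 1 s record")
    data = data[:, : n_records * spr]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    span = np.where(phys_max > phys_min, phys_max - phys_min, 1.0)
    dig_min, dig_max = -32768, 32767
    scaled = (data - phys_min[:, None]) / span[:, None]
    digital = (scaled * (dig_max - dig_min) + dig_min).round().astype("<i2")

    header = b"".join(
        [
            _pad("0", 8),                      # version
            _pad("X X X X", 80),               # patient id (anonymous)
            _pad("Startdate X X X X", 80),     # recording id
            _pad("01.01.20", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + ns)), 8),      # header bytes
            _pad("", 44),                      # reserved
            _pad(str(n_records), 8),
            _pad("1", 8),                      # record duration, seconds
            _pad(str(ns), 4),
        ]
    )
    fields = [
        (labels, 16),
        (["" for _ in range(ns)], 80),                     # transducer
        (["uV" for _ in range(ns)], 8),
        ([f"{v:.6g}" for v in phys_min], 8),
        ([f"{v:.6g}" for v in phys_max], 8),
        ([str(dig_min) for _ in range(ns)], 8),
        ([str(dig_max) for _ in range(ns)], 8),
        (["" for _ in range(ns)], 80),                     # prefiltering
        ([str(spr) for _ in range(ns)], 8),
        (["" for _ in range(ns)], 32),                     # reserved
    ]
    for values, width in fields:
        header += b"".join(_pad(v, width) for v in values)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())
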