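"""File I/O: delimited-text signals, FC matrices with sidecar metadata, manifests.

All persistent artifacts are plain text (delimited matrices, CSV, JSON) so
runs are diffable and portable.  EDF export/import is available when the
optional ``pyedflib`` dependency is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .fc_measures import FCMatrix
from .spectral import BandDefinition

__all__ = [
    "write_signals_text",
    "read_signals_text",
    "write_fc_matrix",
    "read_fc_matrix",
    "write_manifest",
    "read_manifest",
    "write_signals_edf",
    "read_signals_edf",
]


def write_signals_text(path, signals: np.ndarray, fmt: str = "%.8g") -> None:
    """Write a (samples x channels) array as whitespace-delimited text."""
    np.savetxt(path, np.asarray(signals, dtype=float), fmt=fmt)


def read_signals_text(path) -> np.ndarray:
    """Read a (samples x channels) delimited-text array (any whitespace/comma)."""
    text = Path(path).read_text()
    delim = "," if "," in text.splitlines()[0] else None
    return np.loadtxt(path, delimiter=delim, ndmin=2)


def write_fc_matrix(path, m: FCMatrix) -> None:
    """Write an FC matrix as delimited text with a metadata comment line."""
    header = (
        f"measure={m.measure} band={m.band.name} low={m.band.low} "
        f"high={m.band.high} epoch={m.epoch_index if m.epoch_index is not None else -1}"
    )
    np.savetxt(path, m.values, fmt="%.10g", header=header)


def read_fc_matrix(path) -> FCMatrix:
    """Read an FC matrix written by :func:`write_fc_matrix`."""
    first = Path(path).read_text().splitlines()[0]
    if not first.startswith("#"):
        raise ValueError(f"{path}: missing metadata header")
    meta = dict(item.split("=", 1) for item in first[1:].split())
    epoch = int(meta["epoch"])
    return FCMatrix(
        measure=meta["measure"],
        band=BandDefinition(meta["band"], float(meta["low"]), float(meta["high"])),
        values=np.loadtxt(path, ndmin=2),
        epoch_index=None if epoch < 0 else epoch,
    )


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_signals_edf(path, signals: np.ndarray, fs: float, labels=None) -> None:
    """Write signals (samples x channels, mV) to EDF+; requires ``pyedflib``."""
    try:
        import pyedflib
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF export requires the optional dependency pyedflib "
            "(pip install addnet[edf]); delimited-text output is always available"
        ) from exc
    signals = np.asarray(signals, dtype=float)
    n_ch = signals.shape[1]
    labels = labels or [f"ROI_{i + 1}" for i in range(n_ch)]
    writer = pyedflib.EdfWriter(str(path), n_ch, file_type=pyedflib.FILETYPE_EDFPLUS)
    try:
        for i in range(n_ch):
            lo, hi = signals[:, i].min(), signals[:, i].max()
            pad = max(1e-6, 0.01 * (hi - lo))
            writer.setSignalHeader(
                i,
                {
                    "label": labels[i][:16],
                    "dimension": "mV",
                    "sample_frequency": fs,
                    "physical_min": lo - pad,
                    "physical_max": hi + pad,
                    "digital_min": -32768,
                    "digital_max": 32767,
                    "prefilter": "",
                    "transducer": "",
                },
            )
        writer.writeSamples([np.ascontiguousarray(signals[:, i]) for i in range(n_ch)])
    finally:
        writer.close()


def read_signals_edf(path) -> tuple[np.ndarray, float]:
    """Read an EDF file; returns ((samples x channels), fs). Requires ``pyedflib``."""
    try:
        import pyedflib
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF input requires the optional dependency pyedflib") from exc
    with pyedflib.EdfReader(str(path)) as reader:
        fs = float(reader.getSampleFrequencies()[0])
        sig = np.column_stack(
            [reader.readSignal(i) for i in range(reader.signals_in_file)]
        )
    return sig, fs
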