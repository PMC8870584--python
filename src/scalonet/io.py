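"""Reading, writing and validation of multichannel EEG recordings.

A :class:`Recording` is the pipeline's canonical container: a channels x
samples float matrix plus the metadata the downstream stages need (sampling
rate, channel names, subject identity and class label).  Class labels use the
encoding 0 = healthy control (HC), 1 = Parkinson's disease off medication
(PD-OFF), 2 = Parkinson's disease on medication (PD-ON).

Two on-disk representations are supported:

* BrainVision triplets (``.vhdr``/``.vmrk``/``.eeg``), the format the public
  resting-state datasets ship in, read through MNE;
* plain delimited numeric matrices (CSV/TSV) with a JSON sidecar carrying the
  metadata — the portable interchange format used by the synthetic cohorts.

Orientation is channels x samples everywhere; indices are 0-based; the time
axis is in samples with the sampling rate stored separately.  Validation
rejects non-finite values rather than repairing them: no artifact handling is
applied anywhere in the pipeline.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MONTAGE_32",
    "DEFAULT_ANALYSIS_CHANNELS",
    "FormatError",
    "ChannelLookupError",
    "Recording",
    "read_brainvision",
    "read_matrix",
    "write_recording",
    "read_recording",
    "preprocess",
    "select_channels",
]

#: Standard 32-electrode montage (10-20 extended), matching the channel set of
#: the UC San Diego resting-state recordings.
MONTAGE_32 = [
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "Pz", "PO3", "O1", "Oz",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
]

#: The four channels analysed by default (one classifier per channel).
DEFAULT_ANALYSIS_CHANNELS = ["Fp1", "FC1", "CP5", "Fp2"]

VALID_CLASS_LABELS = (0, 1, 2)


class FormatError(ValueError):
    """A file is structurally invalid (ragged rows, non-numeric cells...)."""


class ChannelLookupError(KeyError):
    """A requested channel name is absent from a recording."""

    def __init__(self, missing, available):
        self.missing = list(missing)
        self.available = list(available)
        super().__init__(
            f"channel(s) {self.missing} not found; available channels: "
            f"{self.available}"
        )

    def __str__(self) -> str:  # KeyError quotes its arg; keep it readable
        return self.args[0]


@dataclass
class Recording:
    """One subject's multichannel EEG with labels and channel metadata.

    Parameters
    ----------
    subject_id
        Unique per person; a PD subject's OFF and ON recordings share it.
    class_label
        0 (HC), 1 (PD-OFF) or 2 (PD-ON).
    fs
        Sampling rate in samples per second.
    channel_names
        One name per row of ``samples``, in row order.
    samples
        Channels x time float matrix (microvolts or arbitrary units).
    """

    subject_id: str
    class_label: int
    fs: float
    channel_names: list[str] = field(repr=False)
    samples: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError(
                f"samples must be a 2-D channels x time matrix, got "
                f"{self.samples.ndim} dimension(s)"
            )
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} rows of data"
            )
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if int(self.class_label) not in VALID_CLASS_LABELS:
            raise ValueError(
                f"class_label must be one of {VALID_CLASS_LABELS}, got "
                f"{self.class_label}"
            )
        self.class_label = int(self.class_label)
        if not np.isfinite(self.samples).all():
            bad = int(np.size(self.samples) - np.isfinite(self.samples).sum())
            raise ValueError(
                f"samples contain {bad} non-finite value(s); recordings with "
                "NaN/Inf are rejected rather than repaired"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's 1-D sample vector by electrode name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ChannelLookupError([name], self.channel_names) from None
        return self.samples[idx]


def read_brainvision(
    header_path: str | Path,
    class_label: int,
    subject_id: str | None = None,
) -> Recording:
    """Read a BrainVision ``.vhdr`` triplet into a :class:`Recording`.

    The class label is not stored in BrainVision files; it must be supplied
    by the caller (typically from a BIDS participants table).  Samples are
    returned in microvolts.
    """
    import mne

    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(f"header file not found: {header_path}")
    try:
        raw = mne.io.read_raw_brainvision(
            header_path, preload=True, verbose="error"
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # mne raises assorted types on malformed input
        raise FormatError(f"cannot parse BrainVision file {header_path}: {exc}")
    data = raw.get_data(units="uV")
    return Recording(
        subject_id=subject_id or header_path.stem,
        class_label=class_label,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        samples=data,
    )


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _scan_for_format_error(path: Path, delimiter: str) -> None:
    """Locate and report the first structural defect in a delimited file."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        width = None
        for r, row in enumerate(reader):
            if not row:
                continue
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise FormatError(
                    f"ragged table in {path}: row {r} has {len(row)} fields, "
                    f"expected {width}"
                )
            for c, cell in enumerate(row):
                try:
                    float(cell)
                except ValueError:
                    raise FormatError(
                        f"non-numeric value {cell!r} at row {r}, column {c} "
                        f"of {path} (0-based indices)"
                    ) from None


def read_matrix(
    path: str | Path,
    fs: float,
    channel_names: Sequence[str] | None = None,
    class_label: int = 0,
    subject_id: str | None = None,
    transposed: bool = False,
    delimiter: str | None = None,
) -> Recording:
    """Read a delimited numeric matrix (channels x samples) as a Recording.

    Parameters
    ----------
    transposed
        Set True if the file stores samples x channels; the matrix is
        transposed after parsing so the result is identical to reading its
        channels x samples counterpart.
    delimiter
        Inferred from the extension when omitted (``.tsv`` -> tab, else comma).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    delim = _delimiter_for(path, delimiter)
    try:
        df = pd.read_csv(path, header=None, sep=delim, dtype=np.float64,
                         float_precision="round_trip")
        values = df.to_numpy()
        if np.isnan(values).any():
            # pandas silently NaN-pads short rows; find the real defect.
            _scan_for_format_error(path, delim)
    except (ValueError, pd.errors.ParserError):
        _scan_for_format_error(path, delim)  # raises FormatError with location
        raise  # pragma: no cover - scan found nothing, re-raise original
    if transposed:
        values = values.T
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(values.shape[0])]
    return Recording(
        subject_id=subject_id or path.stem,
        class_label=class_label,
        fs=fs,
        channel_names=list(channel_names),
        samples=values,
    )


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write a recording as a delimited matrix plus a JSON metadata sidecar.

    The matrix is written with 17 significant digits so a read round-trip
    reproduces the samples to full float64 precision.  Returns the sidecar
    path (``<path stem>.json``).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    delim = _delimiter_for(path, None)
    np.savetxt(path, recording.samples, fmt="%.17g", delimiter=delim)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "subject_id": recording.subject_id,
                "class_label": recording.class_label,
                "fs": recording.fs,
                "channels": recording.channel_names,
            },
            indent=2,
        )
    )
    return sidecar


def read_recording(path: str | Path) -> Recording:
    """Read a matrix + JSON sidecar pair written by :func:`write_recording`."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    return read_matrix(
        path,
        fs=meta["fs"],
        channel_names=meta["channels"],
        class_label=meta["class_label"],
        subject_id=meta["subject_id"],
    )


def preprocess(recording: Recording, fn=None) -> Recording:
    """Optional preprocessing hook; the identity by default.

    The pipeline deliberately applies no filtering, re-referencing or
    artifact handling anywhere.  This hook is the single place to slot such
    a step in: ``fn`` receives the channels x samples array and the sampling
    rate and must return an array of the same orientation.
    """
    if fn is None:
        return recording
    return replace(recording, samples=np.asarray(fn(recording.samples,
                                                    recording.fs)))


def select_channels(recording: Recording, names: Sequence[str]) -> Recording:
    """Return a sub-recording containing ``names`` in the requested order."""
    missing = [n for n in names if n not in recording.channel_names]
    if missing:
        raise ChannelLookupError(missing, recording.channel_names)
    idx = [recording.channel_names.index(n) for n in names]
    return replace(
        recording,
        channel_names=[recording.channel_names[i] for i in idx],
        samples=recording.samples[idx],
    )
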