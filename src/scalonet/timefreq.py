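"""Morlet wavelet scalograms and their conversion to 128x128 grayscale tiles.

The time-frequency front end of the pipeline: a single-channel EEG trace is
transformed with the continuous wavelet transform (CWT) using an analytic
Morlet mother wavelet, the magnitude |X(s, tau)| is min-max scaled to [0, 1]
per recording-channel, the 128 lowest scales (= highest frequencies) of the
default 138-scale grid are kept, and the time axis is cut into consecutive
non-overlapping 128-column windows.  Each resulting 128x128 tile is one
training image for the classifier and carries full provenance (subject,
channel, class, tile index) so cross-validation folds can be built per
subject.

Scale is reciprocal to Fourier frequency: with center angular frequency
omega0 (default 6), a dimensionless scale s maps to f = omega0 * fs /
(2 * pi * s) Hz.  Larger scales represent lower frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OMEGA0",
    "Scalogram",
    "TileSet",
    "default_scale_grid",
    "scale_to_frequency",
    "frequency_to_scale",
    "morlet_cwt",
    "morlet_cwt_coefficients",
    "magnitude_normalize",
    "tile_scalogram",
    "export_tiles_png",
    "import_tiles_png",
]

#: Default Morlet center angular frequency (dimensionless).
OMEGA0 = 6.0

MANIFEST_COLUMNS = ["path", "subject_id", "channel", "class_label", "tile_index"]


@dataclass
class Scalogram:
    """CWT magnitude |X(s, tau)| of one channel, scales x time."""

    subject_id: str
    channel: str
    class_label: int
    scales: np.ndarray
    times: np.ndarray
    magnitude: np.ndarray = field(repr=False)
    fs: float = 0.0
    omega0: float = OMEGA0

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=np.float64)
        self.magnitude = np.asarray(self.magnitude)
        if self.magnitude.shape != (self.scales.size, np.asarray(self.times).size):
            raise ValueError(
                f"magnitude shape {self.magnitude.shape} does not match "
                f"{self.scales.size} scales x {np.asarray(self.times).size} times"
            )
        if self.scales.size > 1 and not np.all(np.diff(self.scales) > 0):
            raise ValueError("scales must be strictly increasing")

    @property
    def n_scales(self) -> int:
        return self.scales.size

    @property
    def n_times(self) -> int:
        return self.magnitude.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        """Equivalent Fourier frequency of each scale (Hz, descending)."""
        return scale_to_frequency(self.scales, self.fs, self.omega0)


@dataclass
class TileSet:
    """Labeled 128x128 grayscale tiles with per-tile provenance.

    ``images`` is (n_tiles, h, w) with values in [0, 1]; ``meta`` has one row
    per tile with columns subject_id, channel, class_label, tile_index.
    """

    images: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim != 3:
            raise ValueError("images must be (n_tiles, height, width)")
        if len(self.meta) != self.images.shape[0]:
            raise ValueError("meta must have one row per tile")
        if self.images.size and (
            self.images.min() < 0 or self.images.max() > 1
        ):
            raise ValueError("tile pixel values must lie in [0, 1]")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def labels(self) -> np.ndarray:
        return self.meta["class_label"].to_numpy(dtype=np.int64)

    @property
    def subjects(self) -> np.ndarray:
        return self.meta["subject_id"].to_numpy()

    @classmethod
    def concatenate(cls, tilesets: list["TileSet"]) -> "TileSet":
        tilesets = [t for t in tilesets if len(t)]
        if not tilesets:
            return cls(
                np.zeros((0, 128, 128)),
                pd.DataFrame(columns=MANIFEST_COLUMNS[1:]),
            )
        return cls(
            np.concatenate([t.images for t in tilesets], axis=0),
            pd.concat([t.meta for t in tilesets], ignore_index=True),
        )


def scale_to_frequency(scales, fs: float, omega0: float = OMEGA0) -> np.ndarray:
    """Equivalent Fourier frequency (Hz) of dimensionless Morlet scales."""
    return omega0 * fs / (2.0 * np.pi * np.asarray(scales, dtype=np.float64))


def frequency_to_scale(freqs, fs: float, omega0: float = OMEGA0) -> np.ndarray:
    """Dimensionless Morlet scale whose center frequency is ``freqs`` Hz."""
    return omega0 * fs / (2.0 * np.pi * np.asarray(freqs, dtype=np.float64))


def default_scale_grid(
    fs: float,
    n_scales: int = 138,
    f_min: float = 1.0,
    f_max: float = 60.0,
    omega0: float = OMEGA0,
) -> np.ndarray:
    """Geometric grid of ``n_scales`` scales spanning [f_min, f_max] Hz.

    Scales are returned strictly increasing, so the first ("lowest") scales
    correspond to the highest frequencies.  A single-scale grid sits at the
    geometric midpoint frequency sqrt(f_min * f_max).
    """
    if not 0 < f_min < f_max:
        raise ValueError(f"need 0 < f_min < f_max, got ({f_min}, {f_max})")
    if f_max >= fs / 2:
        raise ValueError(f"f_max {f_max} must be below the Nyquist frequency {fs / 2}")
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    if n_scales == 1:
        freqs = np.array([np.sqrt(f_min * f_max)])
    else:
        freqs = np.geomspace(f_max, f_min, n_scales)
    return frequency_to_scale(freqs, fs, omega0)


def morlet_cwt_coefficients(
    signal, fs: float, scales=None, omega0: float = OMEGA0
) -> np.ndarray:
    """Complex Morlet CWT coefficients X(s, tau), scales x time.

    The linear transform underlying :func:`morlet_cwt`; exposed so linearity
    can be exercised directly (magnitudes alone do not superpose).
    """
    from mne.time_frequency import tfr_array_morlet

    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a non-empty 1-D array")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if scales is None:
        scales = default_scale_grid(fs, omega0=omega0)
    scales = np.asarray(scales, dtype=np.float64)
    if np.any(scales <= 0):
        raise ValueError("all scales must be positive")
    freqs = scale_to_frequency(scales, fs, omega0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coefs = tfr_array_morlet(
            x[None, None, :],
            sfreq=float(fs),
            freqs=freqs,
            n_cycles=omega0,
            output="complex",
            zero_mean=False,
            verbose="error",
        )
    return coefs[0, 0]


def morlet_cwt(
    signal,
    fs: float,
    scales=None,
    omega0: float = OMEGA0,
    subject_id: str = "",
    channel: str = "",
    class_label: int = 0,
) -> Scalogram:
    """Continuous Morlet wavelet transform magnitude of a 1-D signal.

    One output column per input sample; rows follow ``scales`` (ascending,
    i.e. frequency descending).  The convolution zero-pads at the signal
    boundaries and boundary columns are retained (no cone-of-influence
    trimming).  Raises if the signal is shorter than the longest wavelet.
    """
    if scales is None:
        scales = default_scale_grid(fs, omega0=omega0)
    scales = np.asarray(scales, dtype=np.float64)
    magnitude = np.abs(morlet_cwt_coefficients(signal, fs, scales, omega0))
    x = np.asarray(signal)
    return Scalogram(
        subject_id=subject_id,
        channel=channel,
        class_label=class_label,
        scales=scales,
        times=np.arange(x.size),
        magnitude=magnitude,
        fs=float(fs),
        omega0=omega0,
    )


def magnitude_normalize(scalogram: Scalogram) -> Scalogram:
    """Min-max rescale the whole magnitude matrix to [0, 1].

    The scaling frame is the full per-subject-per-channel matrix, so all
    tiles cut from it later share one intensity reference.  A constant
    matrix maps to all zeros (documented degenerate rule).  Idempotent.
    """
    m = scalogram.magnitude
    if not np.isfinite(m).all():
        raise ValueError("magnitude contains NaN/Inf; cannot normalize")
    lo, hi = float(m.min()), float(m.max())
    if hi == lo:
        scaled = np.zeros_like(m, dtype=np.float64)
    else:
        scaled = (m - lo) / (hi - lo)
    return replace(scalogram, magnitude=scaled)


def tile_scalogram(
    scalogram: Scalogram,
    tile_size: int = 128,
    n_keep_scales: int = 128,
    keep: str = "lowest",
) -> TileSet:
    """Cut a normalized scalogram into non-overlapping tile_size^2 tiles.

    Keeps the ``n_keep_scales`` lowest scales (the smallest scale values,
    i.e. the highest frequencies; pass ``keep="highest"`` for the opposite
    reading), then splits the time axis into consecutive windows of
    ``tile_size`` columns, discarding the final partial window.  A scalogram
    shorter than one tile yields an empty TileSet with a warning.
    """
    if n_keep_scales > scalogram.n_scales:
        raise ValueError(
            f"n_keep_scales={n_keep_scales} exceeds the {scalogram.n_scales} "
            "available scales"
        )
    if keep not in ("lowest", "highest"):
        raise ValueError("keep must be 'lowest' or 'highest'")
    m = scalogram.magnitude
    if m.size and (m.min() < 0 or m.max() > 1):
        raise ValueError(
            "scalogram must be normalized to [0, 1] before tiling; "
            "apply magnitude_normalize first"
        )
    kept = m[:n_keep_scales] if keep == "lowest" else m[-n_keep_scales:]
    n_tiles = kept.shape[1] // tile_size
    if n_tiles == 0:
        warnings.warn(
            f"scalogram of width {kept.shape[1]} is shorter than one tile "
            f"({tile_size}); returning an empty TileSet",
            stacklevel=2,
        )
        images = np.zeros((0, n_keep_scales, tile_size))
    else:
        trimmed = kept[:, : n_tiles * tile_size]
        images = np.stack(np.split(trimmed, n_tiles, axis=1))
    meta = pd.DataFrame(
        {
            "subject_id": scalogram.subject_id,
            "channel": scalogram.channel,
            "class_label": scalogram.class_label,
            "tile_index": np.arange(n_tiles, dtype=np.int64),
        }
    )
    return TileSet(images, meta)


def export_tiles_png(tileset: TileSet, out_dir: str | Path) -> pd.DataFrame:
    """Write one 8-bit grayscale PNG per tile plus a CSV manifest.

    Pixels are quantized as round(value * 255); a re-import reproduces them
    to within 1/255.  Returns the manifest (also written as
    ``manifest.csv`` in ``out_dir``).
    """
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(len(tileset)):
        rec = tileset.meta.iloc[i]
        fname = (
            f"{rec.subject_id}_{rec.channel}_c{rec.class_label}"
            f"_t{rec.tile_index:05d}.png"
        )
        path = out_dir / fname
        byte_img = np.round(tileset.images[i] * 255.0).astype(np.uint8)
        Image.fromarray(byte_img, mode="L").save(path)
        rows.append(
            {
                "path": fname,
                "subject_id": rec.subject_id,
                "channel": rec.channel,
                "class_label": int(rec.class_label),
                "tile_index": int(rec.tile_index),
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def import_tiles_png(manifest_path: str | Path) -> TileSet:
    """Load a TileSet back from a manifest written by :func:`export_tiles_png`."""
    from PIL import Image

    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    base = manifest_path.parent
    images = []
    for p in manifest["path"]:
        with Image.open(base / p) as img:
            images.append(np.asarray(img, dtype=np.float64) / 255.0)
    images = (
        np.stack(images) if images else np.zeros((0, 128, 128))
    )
    return TileSet(images, manifest[MANIFEST_COLUMNS[1:]].copy())
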