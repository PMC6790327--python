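"""ROI time-series extraction from 4-D BOLD images and band-pass filtering.

Extraction is the unweighted mean over all voxels sharing an atlas label at
each timepoint. Band-limiting to the standard resting-state range
(0.01-0.1 Hz) uses a zero-phase forward-backward Butterworth filter so
correlations are not distorted by phase shifts.

Registration, segmentation, smoothing and slice-timing are out of scope:
inputs are assumed co-registered to the BOLD grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .timeseries import GM, WM, RoiTimeSeriesSet

logger = logging.getLogger(__name__)

DEFAULT_BAND = (0.01, 0.1)


@dataclass
class AtlasVolume:
    """Integer-label parcellation on the BOLD grid (0 = background)."""

    labels: np.ndarray
    compartment: str
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise ValueError("atlas labels must be integers")
            self.labels = rounded.astype(int)
        if self.labels.ndim != 3:
            raise ValueError("atlas must be a 3-D volume")
        if (self.labels < 0).any():
            raise ValueError("atlas labels must be >= 0")
        if self.compartment not in (WM, GM):
            raise ValueError("compartment must be 'WM' or 'GM'")
        if not self.label_set:
            raise ValueError("atlas contains no nonzero labels")

    @property
    def label_set(self) -> list[int]:
        """Sorted ascending nonzero labels — the canonical ROI order."""
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)

    def name_of(self, label: int) -> str:
        return self.label_names.get(label, f"{self.compartment}_{label:02d}")

    @classmethod
    def from_nifti(
        cls, path, compartment: str, label_names: dict[int, str] | None = None
    ) -> "AtlasVolume":
        import nibabel as nib

        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj), compartment, label_names or {})


def extract_roi_timeseries(
    img_data: np.ndarray, atlas: AtlasVolume, tr_seconds: float
) -> RoiTimeSeriesSet:
    """Average the BOLD signal over each ROI's voxels.

    Parameters
    ----------
    img_data : ndarray, shape (X, Y, Z, T) or a nibabel image
        The 4-D BOLD volume on the same grid as the atlas.
    atlas : AtlasVolume
    tr_seconds : float

    Returns
    -------
    RoiTimeSeriesSet
        One column per nonzero atlas label, in ascending label order. ROIs
        with zero voxels are excluded with a warning, never zero-filled.
    """
    if hasattr(img_data, "dataobj"):  # nibabel image
        img_data = np.asarray(img_data.dataobj)
    img_data = np.asarray(img_data, dtype=float)
    if img_data.ndim != 4:
        raise ValueError("BOLD image must be 4-D (x, y, z, t)")
    if img_data.shape[:3] != atlas.labels.shape:
        raise ValueError(
            f"grid mismatch: image {img_data.shape[:3]} vs atlas {atlas.labels.shape}"
        )
    T = img_data.shape[3]
    flat_img = img_data.reshape(-1, T)
    flat_lab = atlas.labels.reshape(-1)

    cols, labels, counts = [], [], []
    for lab in atlas.label_set:
        mask = flat_lab == lab
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"ROI label {lab} has no voxels; excluded", stacklevel=2)
            continue
        cols.append(flat_img[mask].mean(axis=0))
        labels.append(atlas.name_of(lab))
        counts.append(n)
    if not cols:
        raise ValueError("no ROI had any voxels")
    data = np.column_stack(cols)
    comp = np.array([atlas.compartment] * len(labels), dtype=object)
    return RoiTimeSeriesSet(data, labels, comp, tr_seconds, n_voxels=np.array(counts))


def merge(wm: RoiTimeSeriesSet, gm: RoiTimeSeriesSet) -> RoiTimeSeriesSet:
    """Concatenate WM and GM extractions (WM columns first) into one set."""
    if wm.n_timepoints != gm.n_timepoints:
        raise ValueError("WM and GM series lengths differ")
    if wm.tr_seconds != gm.tr_seconds:
        raise ValueError("WM and GM sampling intervals differ")
    nv = None
    if wm.n_voxels is not None and gm.n_voxels is not None:
        nv = np.concatenate([wm.n_voxels, gm.n_voxels])
    return RoiTimeSeriesSet(
        np.hstack([wm.data, gm.data]),
        wm.roi_labels + gm.roi_labels,
        np.concatenate([wm.compartment, gm.compartment]),
        wm.tr_seconds,
        n_voxels=nv,
    )


def bandpass_array(
    x: np.ndarray, tr_seconds: float, low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1], order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along axis 0; removes column means.

    The filter is order ``order`` per pass and applied forward-backward
    (``filtfilt``), so the effective magnitude response is squared and the
    phase response is identically zero.
    """
    fs = 1.0 / tr_seconds
    nyq = fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for TR={tr_seconds}s "
            f"(Nyquist {nyq:.4g} Hz)"
        )
    x = np.asarray(x, dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    b, a = signal.butter(order, [low_hz, high_hz], btype="band", fs=fs)
    return signal.filtfilt(b, a, x, axis=0)


def bandpass(
    ts: RoiTimeSeriesSet, low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
) -> RoiTimeSeriesSet:
    """Band-limit every ROI column identically; output length = input length."""
    filtered = bandpass_array(ts.data, ts.tr_seconds, low_hz, high_hz)
    return RoiTimeSeriesSet(
        filtered, list(ts.roi_labels), ts.compartment.copy(), ts.tr_seconds,
        n_voxels=None if ts.n_voxels is None else ts.n_voxels.copy(),
    )
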