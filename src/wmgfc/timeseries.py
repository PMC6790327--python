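"""Per-subject ROI time-series container and its CSV interchange format.

A subject is a ``[T timepoints x R ROIs]`` matrix of regional-average BOLD
signal, where each ROI is tagged as white matter (WM) or gray matter (GM).
Column order is the canonical atlas order and is fixed across subjects so
that edge indices are comparable cohort-wide.

On disk a subject is one CSV (rows = timepoints, columns = ROI labels such
as ``WM_01`` .. ``WM_48``, ``GM_01`` .. ``GM_82``); a cohort adds a manifest
JSON mapping subject ids to files and group labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

WM = "WM"
GM = "GM"


@dataclass
class RoiTimeSeriesSet:
    """Regional-average BOLD series for one subject.

    Parameters
    ----------
    data : ndarray, shape (T, R)
        One column per ROI, arbitrary BOLD units. No missing values.
    roi_labels : list of str
        Ordered ROI label strings, canonical across the cohort.
    compartment : ndarray of str, shape (R,)
        Per-ROI tag, ``"WM"`` or ``"GM"``.
    tr_seconds : float
        Sampling interval (fMRI repetition time).
    n_voxels : ndarray of int, optional
        Contributing voxel count per ROI when extracted from an image.
    """

    data: np.ndarray
    roi_labels: list[str]
    compartment: np.ndarray
    tr_seconds: float
    n_voxels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.compartment = np.asarray(self.compartment, dtype=object)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D [T x R] array")
        if self.data.shape[1] != len(self.roi_labels):
            raise ValueError(
                f"{self.data.shape[1]} columns but {len(self.roi_labels)} labels"
            )
        if len(self.compartment) != len(self.roi_labels):
            raise ValueError("compartment tags must match roi_labels")
        bad = set(np.unique(self.compartment)) - {WM, GM}
        if bad:
            raise ValueError(f"unknown compartment tags: {sorted(bad)}")
        if np.isnan(self.data).any():
            raise ValueError("time series contain missing values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def _mask(self, tag: str) -> np.ndarray:
        return self.compartment == tag

    @property
    def wm_labels(self) -> list[str]:
        return [l for l, c in zip(self.roi_labels, self.compartment) if c == WM]

    @property
    def gm_labels(self) -> list[str]:
        return [l for l, c in zip(self.roi_labels, self.compartment) if c == GM]

    def wm_data(self) -> np.ndarray:
        """[T x W] sub-matrix of WM ROI series."""
        return self.data[:, self._mask(WM)]

    def gm_data(self) -> np.ndarray:
        """[T x G] sub-matrix of GM ROI series."""
        return self.data[:, self._mask(GM)]

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.data, columns=self.roi_labels)
        df.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(
        cls, path: str | Path, tr_seconds: float, compartment: np.ndarray | None = None
    ) -> "RoiTimeSeriesSet":
        """Read a subject CSV.

        If ``compartment`` is not given, tags are inferred from the label
        prefix (``WM_*`` -> WM, everything else GM).
        """
        df = pd.read_csv(path)
        labels = [str(c) for c in df.columns]
        if compartment is None:
            compartment = np.array(
                [WM if l.upper().startswith(WM) else GM for l in labels], dtype=object
            )
        return cls(df.to_numpy(dtype=float), labels, compartment, tr_seconds)


def write_cohort(
    subjects: list[tuple[RoiTimeSeriesSet, str]],
    out_dir: str | Path,
    seed: int | None = None,
) -> Path:
    """Write one CSV per subject plus a manifest JSON; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (ts, group) in enumerate(subjects):
        sid = f"sub-{i:03d}"
        fname = f"{sid}.csv"
        ts.to_csv(out_dir / fname)
        entries.append(
            {"subject": sid, "group": group, "file": fname, "tr_seconds": ts.tr_seconds}
        )
    manifest = {"seed": seed, "subjects": entries}
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return mpath


def read_cohort(manifest_path: str | Path) -> list[tuple[RoiTimeSeriesSet, str]]:
    """Load a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    subjects = []
    for e in manifest["subjects"]:
        ts = RoiTimeSeriesSet.from_csv(
            manifest_path.parent / e["file"], tr_seconds=float(e["tr_seconds"])
        )
        subjects.append((ts, str(e["group"])))
    return subjects
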