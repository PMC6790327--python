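"""Static and dynamic (sliding-window RMS) functional connectivity.

Four feature-generating representations are built here:

* ``sGFC``  — static Pearson correlation within gray matter (symmetric G x G);
* ``sWGFC`` — static correlation between every WM and GM ROI pair
  (rectangular W x G);
* ``dGFC`` / ``dWGFC`` — their dynamic counterparts: the full series is cut
  into K overlapping windows (length 30 samples, step 1 by default), the
  per-window correlation C^k is computed for each edge, and the edge is
  summarized by the quadratic mean ``RMS = sqrt(sum_k (C^k)^2 / K)``, which
  measures the fluctuation level of the coupling rather than its average.

Windows are 0-based and half-open: window k covers samples
``[k*step, k*step + window_length)``; ``K = floor((T - window) / step) + 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KIND_STATIC = "static_r"
KIND_RMS = "rms"
KIND_FISHER_Z = "fisher_z"

DEFAULT_WINDOW = 30
DEFAULT_STEP = 1

# |r| is clipped here before the r-to-z transform so numerically perfect
# correlations stay finite.
_Z_CLIP = 1.0 - 1e-7


@dataclass
class FCMatrix:
    """A connectivity matrix with edge metadata.

    ``symmetric=True`` marks a within-compartment matrix (unit diagonal for
    static r); otherwise rows are WM ROIs and columns GM ROIs.
    """

    values: np.ndarray
    kind: str
    row_labels: list[str]
    col_labels: list[str]
    symmetric: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("values shape does not match label lists")
        if self.symmetric and self.row_labels != self.col_labels:
            raise ValueError("symmetric matrix requires identical row/col labels")
        if self.kind == KIND_STATIC and np.abs(self.values).max(initial=0) > 1 + 1e-9:
            raise ValueError("static correlations must lie in [-1, 1]")
        if self.kind == KIND_RMS and (
            (self.values < -1e-12).any() or (self.values > 1 + 1e-9).any()
        ):
            raise ValueError("RMS values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels).to_csv(
            path, float_format="%.12g"
        )


@dataclass
class DynamicFCSeries:
    """Per-edge sequences of K windowed correlations C^1 .. C^K."""

    values: np.ndarray  # [n_edges x K]
    window_length: int
    step: int
    edge_index: list[tuple[str, str]]
    row_labels: list[str]
    col_labels: list[str]
    symmetric: bool
    n_degenerate_windows: int = field(default=0)

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]


def n_windows(n_timepoints: int, window_length: int, step: int) -> int:
    """K = floor((T - window) / step) + 1."""
    if window_length > n_timepoints:
        raise ValueError(
            f"window ({window_length}) longer than series ({n_timepoints})"
        )
    return (n_timepoints - window_length) // step + 1


def _corr_with_degenerate(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Column-wise correlation matrix; zero-variance columns give r = 0."""
    x = x - x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0)
    bad = sd <= 0
    sd_safe = np.where(bad, 1.0, sd)
    xn = x / sd_safe
    r = (xn.T @ xn) / x.shape[0]
    np.clip(r, -1.0, 1.0, out=r)
    if bad.any():
        r[bad, :] = 0.0
        r[:, bad] = 0.0
    return r, int(bad.sum())


def static_fc_within(ts_gm: np.ndarray, labels: list[str]) -> FCMatrix:
    """Symmetric static Pearson-correlation matrix of one ROI set.

    Zero-variance ROIs have all their edges set to 0 (warning logged);
    diagonal is 1.
    """
    ts_gm = np.asarray(ts_gm, dtype=float)
    if ts_gm.shape[0] < 3:
        raise ValueError("need at least 3 timepoints for a correlation")
    r, n_bad = _corr_with_degenerate(ts_gm)
    if n_bad:
        logger.warning("static_fc_within: %d zero-variance ROI(s), edges set to 0", n_bad)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(r, KIND_STATIC, list(labels), list(labels), symmetric=True)


def static_fc_cross(
    ts_wm: np.ndarray, ts_gm: np.ndarray, wm_labels: list[str], gm_labels: list[str]
) -> FCMatrix:
    """Rectangular WM x GM static correlation matrix."""
    ts_wm = np.asarray(ts_wm, dtype=float)
    ts_gm = np.asarray(ts_gm, dtype=float)
    if ts_wm.shape[0] != ts_gm.shape[0]:
        raise ValueError("WM and GM series lengths differ")
    joint = np.hstack([ts_wm, ts_gm])
    r, n_bad = _corr_with_degenerate(joint)
    if n_bad:
        logger.warning("static_fc_cross: %d zero-variance ROI(s), edges set to 0", n_bad)
    w = ts_wm.shape[1]
    # restore exact 1 where a WM column IS a GM column (consistency contract)
    block = r[:w, w:].copy()
    for i in range(w):
        same = np.all(ts_wm[:, [i]] == ts_gm, axis=0)
        block[i, same] = 1.0
    return FCMatrix(block, KIND_STATIC, list(wm_labels), list(gm_labels), symmetric=False)


def dynamic_fc(
    ts_a: np.ndarray,
    ts_b: np.ndarray | None,
    row_labels: list[str],
    col_labels: list[str] | None = None,
    window_length: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> DynamicFCSeries:
    """Sliding-window correlations for every edge.

    With ``ts_b=None`` the edges are the strict upper triangle of
    ``ts_a``'s ROI set (within-compartment); otherwise edges are all
    (row ROI of ts_a) x (column ROI of ts_b) pairs, row-major.

    Each window's correlation is an ordinary Pearson r on that window's
    samples (windows are demeaned implicitly by Pearson). Degenerate
    zero-variance windows yield C^k = 0 and are counted, keeping K
    identical across edges.
    """
    if window_length < 3:
        raise ValueError("window_length must be >= 3")
    ts_a = np.asarray(ts_a, dtype=float)
    symmetric = ts_b is None
    joint = ts_a if symmetric else np.hstack([ts_a, np.asarray(ts_b, dtype=float)])
    t_len = joint.shape[0]
    k_windows = n_windows(t_len, window_length, step)

    w = ts_a.shape[1]
    if symmetric:
        col_labels = list(row_labels)
        iu, ju = np.triu_indices(w, k=1)
        edge_index = [(row_labels[i], row_labels[j]) for i, j in zip(iu, ju)]
    else:
        if col_labels is None:
            raise ValueError("col_labels required for cross-compartment edges")
        edge_index = [(rl, cl) for rl in row_labels for cl in col_labels]

    values = np.empty((len(edge_index), k_windows))
    n_degen = 0
    for k in range(k_windows):
        sl = slice(k * step, k * step + window_length)
        r, nb = _corr_with_degenerate(joint[sl])
        n_degen += nb
        if symmetric:
            values[:, k] = r[iu, ju]
        else:
            values[:, k] = r[:w, w:].reshape(-1)
    if n_degen:
        logger.warning("dynamic_fc: %d degenerate window-ROI pairs (C^k set to 0)", n_degen)
    return DynamicFCSeries(
        values, window_length, step, edge_index, list(row_labels), list(col_labels),
        symmetric, n_degenerate_windows=n_degen,
    )


def rms_over_windows(d: DynamicFCSeries) -> FCMatrix:
    """Quadratic mean over windows per edge, shaped like the static matrix."""
    if d.n_windows < 1:
        raise ValueError("need at least one window")
    rms = np.sqrt(np.mean(d.values**2, axis=1))
    nrow, ncol = len(d.row_labels), len(d.col_labels)
    if d.symmetric:
        m = np.zeros((nrow, ncol))
        iu, ju = np.triu_indices(nrow, k=1)
        m[iu, ju] = rms
        m[ju, iu] = rms
        np.fill_diagonal(m, 1.0)
    else:
        m = rms.reshape(nrow, ncol)
    return FCMatrix(m, KIND_RMS, list(d.row_labels), list(d.col_labels), d.symmetric)


def fisher_z(m: FCMatrix) -> FCMatrix:
    """Elementwise Fisher r-to-z transform, z = (ln(1+r) - ln(1-r)) / 2.

    Applied to static and RMS matrices alike (RMS lies in [0, 1] so z is
    finite after clipping |r| at 1 - 1e-7). Values outside [-1, 1] beyond
    1e-9 are an error.
    """
    v = m.values
    if np.abs(v).max(initial=0) > 1 + 1e-9:
        raise ValueError("correlation values outside [-1, 1]")
    z = np.arctanh(np.clip(v, -_Z_CLIP, _Z_CLIP))
    return FCMatrix(z, KIND_FISHER_Z, list(m.row_labels), list(m.col_labels), m.symmetric)


def vectorize(m: FCMatrix) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Flatten a matrix into the per-subject feature vector.

    Symmetric matrices use the strict upper triangle row-major
    (G ROIs -> G(G-1)/2 features, 82 -> 3321); rectangular matrices flatten
    row-major (48 x 82 -> 3936). The edge index is stable across subjects
    sharing the cohort's canonical label order.
    """
    if m.symmetric:
        n = len(m.row_labels)
        iu, ju = np.triu_indices(n, k=1)
        vec = m.values[iu, ju]
        idx = [(m.row_labels[i], m.col_labels[j]) for i, j in zip(iu, ju)]
    else:
        vec = m.values.reshape(-1)
        idx = [(r, c) for r in m.row_labels for c in m.col_labels]
    return vec, idx


def matrix_from_vector(
    vec: np.ndarray,
    edge_index: list[tuple[str, str]],
    row_labels: list[str],
    col_labels: list[str],
    kind: str,
    symmetric: bool,
    diagonal: float = 1.0,
) -> FCMatrix:
    """Inverse of :func:`vectorize` (diagonal filled for symmetric input)."""
    ri = {l: i for i, l in enumerate(row_labels)}
    ci = {l: i for i, l in enumerate(col_labels)}
    m = np.zeros((len(row_labels), len(col_labels)))
    for v, (a, b) in zip(vec, edge_index):
        m[ri[a], ci[b]] = v
        if symmetric:
            m[ri[b], ci[a]] = v
    if symmetric:
        np.fill_diagonal(m, diagonal)
    return FCMatrix(m, kind, list(row_labels), list(col_labels), symmetric)


def group_mean_fc(matrices: list[FCMatrix]) -> FCMatrix:
    """Elementwise mean of same-shaped, same-kind matrices."""
    if not matrices:
        raise ValueError("empty matrix list")
    m0 = matrices[0]
    for m in matrices[1:]:
        if m.shape != m0.shape or m.kind != m0.kind or m.row_labels != m0.row_labels \
                or m.col_labels != m0.col_labels:
            raise ValueError("matrices differ in shape, kind or labels")
    mean = np.mean([m.values for m in matrices], axis=0)
    return FCMatrix(mean, m0.kind, list(m0.row_labels), list(m0.col_labels), m0.symmetric)


def threshold_mask(m: FCMatrix, thr: float = 0.5) -> np.ndarray:
    """Boolean display mask, |value| strictly greater than the threshold."""
    return np.abs(m.values) > thr
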