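"""Synthetic two-group cohorts of WM+GM ROI time series.

The generator stands in for an access-restricted clinical cohort: two groups
of subjects ("NC" baseline and "AD" carrying injected effects), each subject
a multivariate time series over 48 white-matter and 82 gray-matter ROIs,
band-limited to 0.01-0.1 Hz at TR = 3 s.

Group differences are injected through two distinct channels:

* **static effects** — the stationary correlation on chosen edges differs
  between groups by ``static_effect_delta`` (what static FC detects);
* **dynamic effects** — in the AD group the correlation on chosen edges
  alternates between ``base + a`` and ``base - a`` across connectivity
  regimes with geometric dwell times, leaving the time-averaged correlation
  unchanged but raising the fluctuation that the sliding-window RMS
  statistic measures.

Each regime is a multivariate Gaussian; regime covariances are checked for
positive semidefiniteness and the generator refuses (naming the offending
edges) rather than silently repairing, so injected effects are exactly as
specified. One global seed; per-subject generators are derived from it by
fixed offsets, making subjects independent yet bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .extraction import DEFAULT_BAND, bandpass_array
from .timeseries import GM, WM, RoiTimeSeriesSet

GROUP_CONTROL = "NC"
GROUP_PATIENT = "AD"

Edge = tuple[str, str]


def wm_label(i: int) -> str:
    """1-based WM ROI label, e.g. wm_label(1) == 'WM_01'."""
    return f"{WM}_{i:02d}"


def gm_label(i: int) -> str:
    return f"{GM}_{i:02d}"


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    Attributes
    ----------
    n_per_group : int
        Subjects per group (>= 2).
    n_wm, n_gm : int
        ROI counts per compartment (defaults 48 WM, 82 GM).
    n_timepoints : int
        Samples per series (default 140 volumes, ~7 min at TR 3 s).
    tr_seconds : float
        Sampling interval (default 3.0 s).
    base_correlation : float
        Background inter-ROI correlation, in [0, 1).
    static_effect_edges : tuple of (label, label)
        Edges whose stationary correlation differs between groups.
    static_effect_delta : float
        Correlation difference (AD minus NC) on those edges.
    dynamic_effect_edges : tuple of (label, label)
        Edges whose correlation alternates across regimes in the AD group.
    dynamic_effect_amplitude : float
        Half-range of the regime alternation (correlation units).
    state_dwell : float
        Mean regime dwell time in samples (geometric distribution).
    noise_sd : float
        Additive white measurement noise SD relative to unit signal SD.
        Nonzero noise attenuates observed correlations by 1/(1+noise_sd^2).
    seed : int
        Global RNG seed; identical spec + seed gives bit-identical output.
    """

    n_per_group: int
    n_wm: int = 48
    n_gm: int = 82
    n_timepoints: int = 140
    tr_seconds: float = 3.0
    base_correlation: float = 0.1
    static_effect_edges: tuple[Edge, ...] = ()
    static_effect_delta: float = 0.0
    dynamic_effect_edges: tuple[Edge, ...] = ()
    dynamic_effect_amplitude: float = 0.4
    state_dwell: float = 20.0
    noise_sd: float = 0.0
    seed: int = 0
    band: tuple[float, float] = DEFAULT_BAND

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_wm < 1 or self.n_gm < 1:
            raise ValueError("need at least one ROI per compartment")
        if not (0 <= self.base_correlation < 1):
            raise ValueError("base_correlation must lie in [0, 1)")
        if self.n_timepoints < 10:
            raise ValueError("n_timepoints too small")
        if self.state_dwell < 1:
            raise ValueError("state_dwell must be >= 1 sample")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(
            self, "static_effect_edges", tuple(tuple(e) for e in self.static_effect_edges)
        )
        object.__setattr__(
            self, "dynamic_effect_edges", tuple(tuple(e) for e in self.dynamic_effect_edges)
        )

    # ------------------------------------------------------------- layout

    @property
    def roi_labels(self) -> list[str]:
        return [wm_label(i + 1) for i in range(self.n_wm)] + [
            gm_label(i + 1) for i in range(self.n_gm)
        ]

    @property
    def compartment(self) -> np.ndarray:
        return np.array([WM] * self.n_wm + [GM] * self.n_gm, dtype=object)

    def column_of(self, label: str) -> int:
        try:
            return self.roi_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown ROI label {label!r}") from None


def _apply_edges(sigma: np.ndarray, spec: CohortSpec, edges, value_fn) -> None:
    for a, b in edges:
        i, j = spec.column_of(a), spec.column_of(b)
        if i == j:
            raise ValueError(f"self-edge ({a}, {b}) is not allowed")
        v = value_fn(sigma[i, j])
        sigma[i, j] = sigma[j, i] = v


def regime_covariances(spec: CohortSpec, group: str) -> list[np.ndarray]:
    """The two regime covariance matrices for one group.

    NC: both regimes equal the group's stationary covariance. AD: regimes
    additionally alternate +/- dynamic_effect_amplitude on the dynamic-effect
    edges. Raises ``ValueError`` naming the offending edge set if any implied
    covariance is not positive semidefinite.
    """
    r = spec.n_wm + spec.n_gm
    sigma = np.full((r, r), spec.base_correlation)
    np.fill_diagonal(sigma, 1.0)
    if group == GROUP_PATIENT:
        _apply_edges(
            sigma, spec, spec.static_effect_edges, lambda v: v + spec.static_effect_delta
        )
    regimes = [sigma.copy(), sigma.copy()]
    if group == GROUP_PATIENT and spec.dynamic_effect_edges:
        a = spec.dynamic_effect_amplitude
        _apply_edges(regimes[0], spec, spec.dynamic_effect_edges, lambda v: v + a)
        _apply_edges(regimes[1], spec, spec.dynamic_effect_edges, lambda v: v - a)
    for k, s in enumerate(regimes):
        if np.abs(s).max() > 1 + 1e-12:
            raise ValueError(
                f"group {group} regime {k}: implied correlation exceeds 1 on "
                f"edges {spec.static_effect_edges + spec.dynamic_effect_edges}"
            )
        w = np.linalg.eigvalsh(s)
        if w.min() < -1e-10:
            raise ValueError(
                f"group {group} regime {k} covariance is not positive "
                f"semidefinite (min eigenvalue {w.min():.3g}); offending edges: "
                f"{spec.static_effect_edges + spec.dynamic_effect_edges}"
            )
    return regimes


def _regime_path(rng: np.random.Generator, n: int, dwell: float) -> np.ndarray:
    """Alternating 0/1 regimes with geometric dwell times (mean ``dwell``)."""
    states = np.empty(n, dtype=np.intp)
    t = 0
    s = int(rng.integers(0, 2))
    while t < n:
        d = int(rng.geometric(1.0 / dwell))
        states[t : t + d] = s
        t += d
        s = 1 - s
    return states


def _simulate_subject(
    rng: np.random.Generator, spec: CohortSpec, chols: list[np.ndarray]
) -> np.ndarray:
    t_total = spec.n_timepoints
    states = _regime_path(rng, t_total, spec.state_dwell)
    z = rng.standard_normal((t_total, chols[0].shape[0]))
    x = np.empty_like(z)
    for k in (0, 1):
        m = states == k
        x[m] = z[m] @ chols[k].T
    if spec.noise_sd > 0:
        x = x + spec.noise_sd * rng.standard_normal(x.shape)
    return bandpass_array(x, spec.tr_seconds, *spec.band)


def generate_cohort(spec: CohortSpec) -> list[tuple[RoiTimeSeriesSet, str]]:
    """Generate the full two-group cohort.

    Returns ``2 * n_per_group`` pairs ``(RoiTimeSeriesSet, group_label)``,
    NC subjects first. Each subject draws from its own generator seeded by
    ``(spec.seed, group_index, subject_index)``, so any subject can be
    regenerated independently and the whole cohort is deterministic.
    """
    labels = spec.roi_labels
    comp = spec.compartment
    out: list[tuple[RoiTimeSeriesSet, str]] = []
    for g_idx, group in enumerate((GROUP_CONTROL, GROUP_PATIENT)):
        chols = [
            np.linalg.cholesky(s + 1e-12 * np.eye(s.shape[0]))
            for s in regime_covariances(spec, group)
        ]
        for s_idx in range(spec.n_per_group):
            rng = np.random.default_rng([spec.seed, g_idx, s_idx])
            data = _simulate_subject(rng, spec, chols)
            out.append(
                (RoiTimeSeriesSet(data, list(labels), comp.copy(), spec.tr_seconds), group)
            )
    return out


def default_dynamic_edges(n_edges: int = 50, n_wm: int = 48, n_gm: int = 82) -> tuple[Edge, ...]:
    """A standard WM-GM effect edge set: distinct GM targets, WM reused at
    most ceil(n_edges/n_wm) times, keeping the perturbed covariance well
    conditioned."""
    if n_edges > n_gm:
        raise ValueError("need n_edges <= n_gm for distinct GM targets")
    return tuple(
        (wm_label(i % n_wm + 1), gm_label(i + 1)) for i in range(n_edges)
    )


def render_image_fixture(
    subject: RoiTimeSeriesSet,
    shape: tuple[int, int, int],
    voxels_per_roi: int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Expand an ROI series set into a 4-D image plus paired WM/GM atlases.

    Every voxel of ROI ``k`` carries that ROI's series plus independent
    Gaussian noise. Returns ``(img_4d, gm_atlas, wm_atlas)`` where the
    atlases are :class:`~wmgfc.extraction.AtlasVolume` with integer labels
    in the subject's canonical order (WM labels 1..W, GM labels 1..G).

    Raises ``ValueError`` if the grid has too few voxels.
    """
    from .extraction import AtlasVolume

    n_vox = int(np.prod(shape))
    needed = subject.n_rois * voxels_per_roi
    if needed > n_vox:
        raise ValueError(
            f"grid {shape} has {n_vox} voxels; need {needed} for "
            f"{subject.n_rois} ROIs x {voxels_per_roi}"
        )
    rng = np.random.default_rng(seed)
    t_len = subject.n_timepoints
    flat_img = np.zeros((n_vox, t_len))
    flat_wm = np.zeros(n_vox, dtype=int)
    flat_gm = np.zeros(n_vox, dtype=int)

    pos = 0
    wm_count = gm_count = 0
    wm_names: dict[int, str] = {}
    gm_names: dict[int, str] = {}
    for r in range(subject.n_rois):
        series = subject.data[:, r]
        sl = slice(pos, pos + voxels_per_roi)
        block = np.tile(series, (voxels_per_roi, 1))
        if noise_sd > 0:
            block = block + noise_sd * rng.standard_normal(block.shape)
        flat_img[sl] = block
        if subject.compartment[r] == WM:
            wm_count += 1
            flat_wm[sl] = wm_count
            wm_names[wm_count] = subject.roi_labels[r]
        else:
            gm_count += 1
            flat_gm[sl] = gm_count
            gm_names[gm_count] = subject.roi_labels[r]
        pos += voxels_per_roi

    img = flat_img.reshape(*shape, t_len)
    gm_atlas = AtlasVolume(flat_gm.reshape(shape), GM, gm_names) if gm_count else None
    wm_atlas = AtlasVolume(flat_wm.reshape(shape), WM, wm_names) if wm_count else None
    return img, gm_atlas, wm_atlas


def save_image_fixture(img: np.ndarray, atlas, path_img, path_atlas) -> None:
    """Round-trip helper: write the rendered image and atlas as NIfTI."""
    import nibabel as nib

    affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(img, dtype=np.float32), affine), str(path_img))
    nib.save(
        nib.Nifti1Image(np.asarray(atlas.labels, dtype=np.int16), affine), str(path_atlas)
    )
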