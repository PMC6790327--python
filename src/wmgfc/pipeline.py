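"""End-to-end orchestration: cohort -> connectivity -> selection -> SVM -> report.

A run consumes either a simulated cohort, per-subject ROI-series CSVs, or
4-D BOLD images with paired WM/GM atlases, and produces for each of the
four connectivity methods (sGFC, sWGFC, dGFC, dWGFC): the per-subject
feature table, the edge statistics, LOO classification metrics with ROC
points, plus cohort-level reports (group-mean thresholded FC masks, a
selection-threshold sweep, the top-k FDR-reported edges of dWGFC, and a
one-row-per-method summary). A manifest records the config hash, seed and
package versions so every output is reproducible bit-for-bit from
(config, seed, inputs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassificationResult, loo_svm
from .connectivity import (
    DEFAULT_STEP,
    DEFAULT_WINDOW,
    dynamic_fc,
    fisher_z,
    group_mean_fc,
    rms_over_windows,
    static_fc_cross,
    static_fc_within,
    threshold_mask,
    vectorize,
)
from .extraction import DEFAULT_BAND, AtlasVolume, bandpass, extract_roi_timeseries, merge
from .features import (
    DEFAULT_ALPHA_DYNAMIC,
    DEFAULT_ALPHA_STATIC,
    DEFAULT_FDR_Q,
    edge_ttest,
    select_edges,
    threshold_sweep,
    top_edges,
)
from .simulate import CohortSpec, generate_cohort
from .timeseries import RoiTimeSeriesSet, read_cohort

logger = logging.getLogger(__name__)

METHODS = ("sGFC", "sWGFC", "dGFC", "dWGFC")
STATIC_METHODS = ("sGFC", "sWGFC")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    Round-trips unchanged through YAML (:meth:`to_yaml` / :meth:`from_yaml`).
    """

    mode: str = "simulate"  # simulate | series | images
    cohort_manifest: str | None = None
    window_length: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP
    band: tuple[float, float] = DEFAULT_BAND
    alphas: tuple[float, ...] = (0.05, 0.01, 0.001)
    alpha_static: float = DEFAULT_ALPHA_STATIC
    alpha_dynamic: float = DEFAULT_ALPHA_DYNAMIC
    protocol: str = "nested"
    svm_cost: float = 1.0
    standardize: bool = False
    test_variant: str = "pooled"
    min_features: int = 0
    fdr_q: float = DEFAULT_FDR_Q
    display_threshold: float = 0.5
    top_k: int = 15
    seed: int = 0
    out_dir: str = "wmgfc_run"
    bandpass_series_input: bool = False
    run_sweep: bool = True
    sweep_method: str = "dWGFC"
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "series", "images"):
            raise ValueError("mode must be simulate, series or images")
        if self.window_length < 3 or self.step < 1:
            raise ValueError("window_length >= 3 and step >= 1 required")
        if not (0 < self.band[0] < self.band[1]):
            raise ValueError("band must satisfy 0 < low < high")
        for name in ("alpha_static", "alpha_dynamic", "fdr_q"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.svm_cost <= 0:
            raise ValueError("svm_cost must be positive")
        if self.display_threshold < 0:
            raise ValueError("display_threshold must be >= 0")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        self.band = tuple(self.band)
        self.alphas = tuple(self.alphas)

    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, tuple):
                return [plain(x) for x in v]
            if isinstance(v, list):
                return [plain(x) for x in v]
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            return v

        return {k: plain(v) for k, v in dataclasses.asdict(self).items()}

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Hash of everything that affects the numbers (out_dir excluded)."""
        d = self.to_dict()
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ----------------------------------------------------------------- stages


def load_cohort(cfg: RunConfig) -> list[tuple[RoiTimeSeriesSet, str]]:
    """Stage 1: obtain the cohort for any of the three input modes."""
    if cfg.mode == "simulate":
        spec = CohortSpec(seed=cfg.seed, band=cfg.band, **cfg.simulate)
        return generate_cohort(spec)
    if cfg.cohort_manifest is None:
        raise FileNotFoundError("cohort_manifest is required in series/images mode")
    mpath = Path(cfg.cohort_manifest)
    if not mpath.exists():
        raise FileNotFoundError(f"cohort manifest not found: {mpath}")
    if cfg.mode == "series":
        cohort = read_cohort(mpath)
        if cfg.bandpass_series_input:
            cohort = [(bandpass(ts, *cfg.band), g) for ts, g in cohort]
        return cohort
    # images mode: manifest lists bold/wm_atlas/gm_atlas NIfTI paths per subject
    import nibabel as nib

    manifest = json.loads(mpath.read_text())
    cohort = []
    for e in manifest["subjects"]:
        base = mpath.parent
        wm_atlas = AtlasVolume.from_nifti(base / e["wm_atlas"], "WM")
        gm_atlas = AtlasVolume.from_nifti(base / e["gm_atlas"], "GM")
        img = nib.load(str(base / e["bold"]))
        tr = float(e.get("tr_seconds", manifest.get("tr_seconds", 3.0)))
        ts = merge(
            extract_roi_timeseries(img, wm_atlas, tr),
            extract_roi_timeseries(img, gm_atlas, tr),
        )
        cohort.append((bandpass(ts, *cfg.band), str(e["group"])))
    return cohort


def subject_features(
    ts: RoiTimeSeriesSet, window_length: int, step: int
) -> dict[str, tuple[np.ndarray, list, object]]:
    """Stage 2 for one subject: the four Fisher-z feature vectors.

    Returns method -> (feature vector, edge_index, raw FCMatrix).
    """
    gm = ts.gm_data()
    wm = ts.wm_data()
    gml, wml = ts.gm_labels, ts.wm_labels
    out = {}
    m = static_fc_within(gm, gml)
    vec, idx = vectorize(fisher_z(m))
    out["sGFC"] = (vec, idx, m)
    m = static_fc_cross(wm, gm, wml, gml)
    vec, idx = vectorize(fisher_z(m))
    out["sWGFC"] = (vec, idx, m)
    d = dynamic_fc(gm, None, gml, window_length=window_length, step=step)
    m = rms_over_windows(d)
    vec, idx = vectorize(fisher_z(m))
    out["dGFC"] = (vec, idx, m)
    d = dynamic_fc(wm, gm, wml, gml, window_length=window_length, step=step)
    m = rms_over_windows(d)
    vec, idx = vectorize(fisher_z(m))
    out["dWGFC"] = (vec, idx, m)
    return out


def cohort_features(
    cohort: list[tuple[RoiTimeSeriesSet, str]], window_length: int, step: int
) -> tuple[dict[str, np.ndarray], dict[str, list], dict[str, list], np.ndarray]:
    """Stack per-subject features: method -> [n_subjects x n_edges].

    Also returns method -> edge_index, method -> raw per-subject matrices,
    and the label array. All four methods see identical subject order.
    """
    feats: dict[str, list[np.ndarray]] = {m: [] for m in METHODS}
    raws: dict[str, list] = {m: [] for m in METHODS}
    edge_idx: dict[str, list] = {}
    labels = []
    for ts, group in cohort:
        per = subject_features(ts, window_length, step)
        for m in METHODS:
            vec, idx, raw = per[m]
            feats[m].append(vec)
            raws[m].append(raw)
            if m in edge_idx and edge_idx[m] != idx:
                raise ValueError(f"{m}: subject edge order differs from cohort canon")
            edge_idx[m] = idx
        labels.append(group)
    stacked = {m: np.vstack(feats[m]) for m in METHODS}
    return stacked, edge_idx, raws, np.asarray(labels)


def classify_method(
    cfg: RunConfig, method: str, features: np.ndarray, labels: np.ndarray, edge_index
) -> ClassificationResult:
    alpha = cfg.alpha_static if method in STATIC_METHODS else cfg.alpha_dynamic
    return loo_svm(
        features, labels, edge_index, alpha=alpha, protocol=cfg.protocol,
        c_cost=cfg.svm_cost, standardize=cfg.standardize,
        test_variant=cfg.test_variant, min_features=cfg.min_features, method=method,
    )


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages and write the run directory; returns its path.

    Outputs are written as each stage completes, so a failed run leaves
    the finished stages on disk for inspection and re-use.
    """
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")

    cohort = load_cohort(cfg)
    labels_arr = np.array([g for _, g in cohort])
    classes = sorted(set(labels_arr))
    logger.info("cohort: %d subjects, groups %s", len(cohort), classes)

    feats, edge_idx, raws, labels_arr = cohort_features(
        cohort, cfg.window_length, cfg.step
    )

    summary_rows = []
    for method in METHODS:
        mdir = out / method
        mdir.mkdir(exist_ok=True)
        x = feats[method]
        idx = edge_idx[method]
        edge_names = [f"{a}|{b}" for a, b in idx]
        pd.DataFrame(x, columns=edge_names).assign(group=labels_arr).to_csv(
            mdir / "features.csv", index=False, float_format="%.10g"
        )
        alpha = cfg.alpha_static if method in STATIC_METHODS else cfg.alpha_dynamic
        st = edge_ttest(
            x[labels_arr == "AD"], x[labels_arr == "NC"], idx, variant=cfg.test_variant
        )
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            st = select_edges(st, alpha)
        st.to_frame().to_csv(mdir / "edge_stats.csv", index=False, float_format="%.10g")

        # group-mean raw FC and display masks (|value| > display_threshold)
        for group in ("NC", "AD"):
            mats = [raw for raw, g in zip(raws[method], labels_arr) if g == group]
            gm_mean = group_mean_fc(mats)
            gm_mean.to_csv(mdir / f"group_mean_{group}.csv")
            mask = threshold_mask(gm_mean, cfg.display_threshold).astype(int)
            pd.DataFrame(
                mask, index=gm_mean.row_labels, columns=gm_mean.col_labels
            ).to_csv(mdir / f"group_mask_{group}.csv")

        res = classify_method(cfg, method, x, labels_arr, idx)
        (mdir / "metrics.json").write_text(
            json.dumps(
                {
                    "method": method, "protocol": res.protocol, "alpha": res.alpha,
                    "seed": cfg.seed, "metrics": res.metrics.as_dict(),
                    "n_features_per_fold": res.n_features_per_fold,
                },
                indent=2, sort_keys=True,
            )
            + "\n"
        )
        res.predictions_frame().to_csv(
            mdir / "predictions.csv", index=False, float_format="%.10g"
        )
        pd.DataFrame(res.roc, columns=["FPR", "TPR"]).to_csv(
            mdir / "roc.csv", index=False, float_format="%.10g"
        )
        summary_rows.append(res.summary_row())
        logger.info("%s done: ACC=%.2f%%", method, res.acc)

        if method == "dWGFC":
            top_edges(st, cfg.top_k).to_csv(
                mdir / f"top_{cfg.top_k}_edges.csv", index=False, float_format="%.10g"
            )

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "summary.csv", index=False, float_format="%.10g")

    if cfg.run_sweep and len(cfg.alphas) >= 1:
        sw = threshold_sweep(
            feats[cfg.sweep_method], labels_arr, edge_idx[cfg.sweep_method],
            list(cfg.alphas), protocol=cfg.protocol, c_cost=cfg.svm_cost,
            standardize=cfg.standardize, test_variant=cfg.test_variant,
            min_features=cfg.min_features, method=cfg.sweep_method,
        )
        sw.to_csv(out / "sweep.csv", index=False, float_format="%.10g")

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_subjects": len(cohort),
        "groups": {c: int((labels_arr == c).sum()) for c in classes},
        "versions": {"wmgfc": __version__, "numpy": np.__version__},
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    logger.info("run complete in %.1f s", time.time() - t0)
    return out
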