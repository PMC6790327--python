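"""Edge-wise group statistics and feature selection.

Subjects' Fisher-z connectivity features are compared edge by edge with a
two-sample t test (pooled-variance Student by default, Welch optional).
Selection for the classifier uses a raw p-value threshold (non-strict,
p <= alpha); Benjamini-Hochberg FDR correction is computed for reporting
the top edges, not for selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_STATIC = 0.001
DEFAULT_ALPHA_DYNAMIC = 0.01
DEFAULT_FDR_Q = 0.05


@dataclass
class EdgeStats:
    """Per-edge two-group test results.

    ``selected`` is the mask at threshold ``alpha`` (empty until
    :func:`select_edges` is applied).
    """

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    selected: np.ndarray
    alpha: float | None
    edge_index: list[tuple[str, str]]

    @property
    def n_edges(self) -> int:
        return len(self.p)

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def to_frame(self) -> pd.DataFrame:
        rows, cols = zip(*self.edge_index)
        return pd.DataFrame(
            {
                "row_roi": rows,
                "col_roi": cols,
                "t": self.t,
                "p": self.p,
                "q": self.q,
                "selected": self.selected.astype(int),
            }
        )


def edge_ttest(
    features_a: np.ndarray,
    features_b: np.ndarray,
    edge_index: list[tuple[str, str]],
    variant: str = "pooled",
) -> EdgeStats:
    """Two-sample t test at every edge.

    Parameters
    ----------
    features_a, features_b : ndarray, [n_subjects x n_edges]
        Fisher-z features of the two groups (same edge order).
    variant : {"pooled", "welch"}
        Pooled-variance Student t (nA+nB-2 d.f.) or Welch.

    Edges with zero pooled variance get t = 0, p = 1 (logged).
    """
    a = np.asarray(features_a, dtype=float)
    b = np.asarray(features_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("feature matrices must be 2-D with equal edge counts")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if a.shape[1] != len(edge_index):
        raise ValueError("edge_index length does not match feature count")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=(variant == "pooled"))
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    bad = ~np.isfinite(t)
    if bad.any():
        logger.warning("edge_ttest: %d edge(s) with zero variance; p set to 1", bad.sum())
        t[bad] = 0.0
        p[bad] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = fdr_correct(p)
    return EdgeStats(
        t=t, p=p, q=q, selected=np.zeros(len(p), dtype=bool), alpha=None,
        edge_index=list(edge_index),
    )


def select_edges(stats_in: EdgeStats, alpha: float) -> EdgeStats:
    """Mark edges with p <= alpha (non-strict) as the classifier feature set."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    mask = stats_in.p <= alpha
    if not mask.any():
        warnings.warn(
            f"no edge passes p <= {alpha}; selection is empty", stacklevel=2
        )
    return replace(stats_in, selected=mask, alpha=alpha)


def fdr_correct(p: np.ndarray, q: float = DEFAULT_FDR_Q) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    The adjusted values do not depend on ``q``; the parameter records the
    conventional reporting level.
    """
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[1]


def top_edges(stats_in: EdgeStats, k: int = 15) -> pd.DataFrame:
    """The k edges with smallest p, as a ranked (row ROI, col ROI, p, q) table.

    Ties in p break by |t| descending, then by edge-index position, so the
    ranking is deterministic across runs.
    """
    n = stats_in.n_edges
    if k > n:
        warnings.warn(f"requested top {k} of only {n} edges; returning all", stacklevel=2)
        k = n
    order = sorted(range(n), key=lambda i: (stats_in.p[i], -abs(stats_in.t[i]), i))[:k]
    rows = [
        {
            "row_roi": stats_in.edge_index[i][0],
            "col_roi": stats_in.edge_index[i][1],
            "t": stats_in.t[i],
            "p": stats_in.p[i],
            "q": stats_in.q[i],
        }
        for i in order
    ]
    return pd.DataFrame(rows)


def threshold_sweep(
    features: np.ndarray,
    labels: np.ndarray,
    edge_index: list[tuple[str, str]],
    alphas: list[float],
    protocol: str = "nested",
    **svm_kwargs,
) -> pd.DataFrame:
    """Leave-one-out accuracy at each candidate selection threshold.

    Runs the classification stage once per alpha; classifier failures for a
    given alpha (e.g. empty selection) are recorded as missing rather than
    aborting the sweep. Returns a table with columns ``alpha``, ``accuracy``,
    ``n_selected`` and an ``argmax`` flag on the best row.
    """
    from .classify import loo_svm  # local import to avoid a module cycle

    if len(alphas) < 1:
        raise ValueError("need at least one alpha")
    rows = []
    for alpha in alphas:
        try:
            res = loo_svm(features, labels, edge_index, alpha=alpha,
                          protocol=protocol, **svm_kwargs)
            rows.append(
                {"alpha": alpha, "accuracy": res.acc,
                 "n_selected": float(np.mean(res.n_features_per_fold))}
            )
        except ValueError as exc:
            logger.warning("sweep: alpha=%g failed (%s)", alpha, exc)
            rows.append({"alpha": alpha, "accuracy": np.nan, "n_selected": np.nan})
    table = pd.DataFrame(rows)
    table["argmax"] = False
    if table["accuracy"].notna().any():
        table.loc[table["accuracy"].idxmax(), "argmax"] = True
    return table
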