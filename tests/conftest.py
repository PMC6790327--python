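import numpy as np
import pytest

from wmgfc.simulate import CohortSpec, generate_cohort


def brute_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson r, written independently of the package."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.mean()
    dy = y - y.mean()
    return float(np.sum(dx * dy) / np.sqrt(np.sum(dx**2) * np.sum(dy**2)))


def pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Hand-written pooled-variance two-sample t with nA+nB-2 d.f."""
    from scipy.stats import t as t_dist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * t_dist.sf(abs(t), na + nb - 2)
    return float(t), float(p)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up by hand (independent of statsmodels)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


@pytest.fixture(scope="session")
def tiny_spec():
    return CohortSpec(
        n_per_group=4, n_wm=3, n_gm=5, n_timepoints=60, state_dwell=10.0, seed=7
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)
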