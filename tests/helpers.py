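"""Shared builders for estimator-level tests."""

import numpy as np

from mrld.summary_io import HarmonizedSet, LDMatrix


def make_harmonized(beta_x, beta_y, se_y, rho=None, se_x=None, p_x=None,
                    pos=None, ids=None) -> HarmonizedSet:
    """Assemble a HarmonizedSet from raw vectors."""
    beta_x = np.asarray(beta_x, dtype=float)
    k = len(beta_x)
    ids = ids if ids is not None else [f"rs{i + 1}" for i in range(k)]
    rho = np.eye(k) if rho is None else np.asarray(rho, dtype=float)
    se_x = np.full(k, 0.01) if se_x is None else np.asarray(se_x, dtype=float)
    if p_x is None:
        from scipy.stats import norm
        p_x = 2 * norm.sf(np.abs(beta_x / se_x))
    return HarmonizedSet(
        variant_ids=list(ids),
        beta_exposure=beta_x,
        se_exposure=se_x,
        p_exposure=np.asarray(p_x, dtype=float),
        beta_outcome=np.asarray(beta_y, dtype=float),
        se_outcome=np.asarray(se_y, dtype=float),
        ld=LDMatrix(list(ids), rho),
        pos=pos,
    )


def random_correlation(rng, k, shrink=0.6):
    """A well-conditioned random correlation matrix (shrunk toward identity)."""
    a = rng.normal(size=(k, k))
    s = a @ a.T + k * np.eye(k) * 1e-3
    d = np.sqrt(np.diag(s))
    r = s / np.outer(d, d)
    return (1 - shrink) * r + shrink * np.eye(k)


def gls_oracle(x, y, se, rho):
    """Independent explicit-inverse GLS reference implementation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    se = np.asarray(se, float)
    sigma = np.diag(se) @ np.asarray(rho, float) @ np.diag(se)
    si = np.linalg.inv(sigma)
    var = 1.0 / float(x @ si @ x)
    theta = var * float(x @ si @ y)
    return theta, var ** 0.5


def greedy_oracle(ids, pvals, pos, r, r2_max):
    """Independent re-coding of p-ranked greedy selection with r² pruning.

    Repeatedly picks the smallest-(p, pos, id) candidate still compatible
    (r² below the ceiling) with everything selected so far.
    """
    import math

    remaining = {
        i: (pvals[i], pos[i] if pos is not None and not math.isnan(pos[i]) else math.inf,
            ids[i])
        for i in range(len(ids))
    }
    chosen = []
    while remaining:
        i = min(remaining, key=remaining.get)
        chosen.append(i)
        del remaining[i]
        for j in list(remaining):
            if r[i][j] ** 2 >= r2_max:
                del remaining[j]
    return [ids[i] for i in chosen]
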