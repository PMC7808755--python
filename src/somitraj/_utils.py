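"""Small shared numerics used across the pipeline."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs pass through as NaN."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.sum() == 0:
        return out
    out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def softplus(x: np.ndarray) -> np.ndarray:
    """log(1+exp(x)) computed without overflow."""
    x = np.asarray(x, dtype=float)
    return np.logaddexp(0.0, x)


def check_positive(name: str, value) -> None:
    if not np.all(np.asarray(value) > 0):
        raise ValueError(f"{name} must be positive, got {value!r}")


def as_dense(mat) -> np.ndarray:
    """Dense float array from a scipy sparse matrix or array-like."""
    if hasattr(mat, "toarray"):
        return np.asarray(mat.toarray(), dtype=float)
    return np.asarray(mat, dtype=float)
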