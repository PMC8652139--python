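"""Per-sample T-scores: the signed pooled-variance two-sample t statistic.

Within one sample, the expression values of the up-regulated signature
homologs are compared with those of the down-regulated homologs by an
equal-variance two-tailed t-test.  The T-score is

    T = d * TINV(p, df)

with d = +1 when the up group's mean exceeds the down group's mean and -1
otherwise, p the two-tailed p-value, and df = n_up + n_down - 2.  Because
TINV(p, df) is the two-tailed inverse of the central t distribution, this
reconstruction is algebraically identical to the signed pooled t statistic
itself; the identity is property-tested.  A positive score means the sample
expresses the signature — a surrogate for the upstream regulator being
active in that sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix
from .preprocess import ProjectedSignature

__all__ = ["tscore_sample", "compute_tscores", "classify_activity"]


class DegenerateGroupError(ValueError):
    """Raised when a t-test group is too small or has zero pooled variance."""


def _pooled_t(up: np.ndarray, down: np.ndarray) -> tuple[float, float, int]:
    """Pooled-variance t statistic, two-tailed p and df for one sample."""
    n1, n2 = up.shape[0], down.shape[0]
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * up.var(ddof=1) + (n2 - 1) * down.var(ddof=1)) / df
    if sp2 <= 0.0:
        raise DegenerateGroupError("zero pooled variance: all gene values identical")
    t = (up.mean() - down.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), df


def tscore_sample(
    up_values: np.ndarray, down_values: np.ndarray
) -> tuple[float, float, int]:
    """T-score, two-tailed p-value and df for a single sample.

    Parameters are the centered expression values of the up- and
    down-signature homologs in that sample; each group needs at least two
    genes.  Returns ``(tscore, pvalue, df)`` with
    ``tscore = d * TINV(pvalue, df)``.
    """
    up = np.asarray(up_values, dtype=float)
    down = np.asarray(down_values, dtype=float)
    if up.ndim != 1 or down.ndim != 1:
        raise ValueError("up/down values must be 1-D vectors")
    if up.shape[0] < 2 or down.shape[0] < 2:
        raise DegenerateGroupError(
            f"need >=2 genes per direction, got {up.shape[0]} up / {down.shape[0]} down"
        )
    t, p, df = _pooled_t(up, down)
    d = 1.0 if up.mean() >= down.mean() else -1.0
    # two-tailed inverse: positive t with P(|T| > t) = p
    tinv = stats.t.isf(p / 2.0, df)
    return float(d * tinv), p, df


def compute_tscores(
    matrix: ExpressionMatrix, sig: ProjectedSignature
) -> pd.DataFrame:
    """T-score table for every sample of a median-centered gene-level matrix.

    Vectorised over samples; equivalent to calling :func:`tscore_sample`
    column by column.  Returns a DataFrame indexed by ``sample_id`` with
    columns ``tscore, pvalue, n_up, n_down, df``.
    """
    if matrix.level != "gene":
        raise ValueError("compute_tscores expects a gene-level matrix")
    up_ids = sorted(sig.up_homologs)
    down_ids = sorted(sig.down_homologs)
    n1, n2 = len(up_ids), len(down_ids)
    if n1 < 2 or n2 < 2:
        raise DegenerateGroupError(
            f"need >=2 homologs per direction in the matrix, got {n1} up / {n2} down"
        )
    missing = (set(up_ids) | set(down_ids)) - set(matrix.row_ids)
    if missing:
        raise ValueError(f"signature homologs absent from matrix: {sorted(missing)[:5]}")

    up = matrix.data.loc[up_ids].to_numpy()      # n1 x S
    down = matrix.data.loc[down_ids].to_numpy()  # n2 x S
    df = n1 + n2 - 2
    m1, m2 = up.mean(axis=0), down.mean(axis=0)
    v1, v2 = up.var(axis=0, ddof=1), down.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    bad = sp2 <= 0.0
    if bad.any():
        sample = matrix.sample_ids[int(np.argmax(bad))]
        raise DegenerateGroupError(
            f"zero pooled variance in sample {sample!r}: all gene values identical"
        )
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    d = np.where(m1 >= m2, 1.0, -1.0)
    tscore = d * stats.t.isf(p / 2.0, df)
    return pd.DataFrame(
        {
            "tscore": tscore,
            "pvalue": p,
            "n_up": n1,
            "n_down": n2,
            "df": df,
        },
        index=pd.Index(matrix.sample_ids, name="sample_id"),
    )


def classify_activity(tscore: float) -> str:
    """``'active'`` for a strictly positive T-score, else ``'inactive'``."""
    return "active" if tscore > 0 else "inactive"
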