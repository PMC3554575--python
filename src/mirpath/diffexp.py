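"""Feature-level differential expression: Student t-test plus Benjamini-
Hochberg FDR, used for differentially expressed miRs and for annotating
results."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import fdrcorrection

from .data_io import ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass
class DEResult:
    feature_id: str
    t: float
    p: float
    q: float = float("nan")
    is_de: bool = False


def t_test_features(data: ExpressionDataset) -> list[DEResult]:
    """Two-sided equal-variance (Student) t-test per feature.

    Degenerate features with zero pooled variance report t = 0, p = 1 when
    the class means are equal, and the p = 0 convention (logged) when they
    differ — an infinite separation in the equal-variance model.
    """
    disease, control = data.class_masks()
    if disease.sum() < 2 or control.sum() < 2:
        raise ValueError("need >=2 samples per class")
    values = data.matrix()
    x, y = values[:, disease], values[:, control]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(x, y, axis=1, equal_var=True)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t) | ~np.isfinite(p)
    if degenerate.any():
        eq = np.isclose(x.mean(axis=1), y.mean(axis=1))
        n_sep = int((degenerate & ~eq).sum())
        if n_sep:
            logger.info("t_test_features: %d zero-variance features with unequal means -> p=0", n_sep)
        t[degenerate] = 0.0
        p[degenerate & eq] = 1.0
        p[degenerate & ~eq] = 0.0
    return [
        DEResult(feature_id=f, t=float(ti), p=float(pi))
        for f, ti, pi in zip(data.feature_ids, t, p)
    ]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q = fdrcorrection(p, method="indep")
    return np.minimum(q, 1.0)


def differential_expression(data: ExpressionDataset, alpha_fdr: float = 0.01) -> list[DEResult]:
    """t-test plus BH correction; a feature is DE when q < ``alpha_fdr``."""
    results = t_test_features(data)
    q = bh_fdr([r.p for r in results])
    for r, qi in zip(results, q):
        r.q = float(qi)
        r.is_de = bool(qi < alpha_fdr)
    return results
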