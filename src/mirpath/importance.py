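"""Random-forest regression of pathway enrichment scores on miR Z-profiles,
with permutation-calibrated local importance.

Each regression tree is grown on a without-replacement subsample of
pathways (cases) with a random subset of miR features per split. The local
importance of miR m for pathway p is the Breiman-style per-case score: the
mean, over trees where p is out-of-bag, of the increase in the tree's
squared prediction error for p when feature m is permuted among the
out-of-bag cases. Significance is calibrated against a permutation null in
which enrichment scores and each miR's profile are shuffled independently
across pathways; per-pair null mean and sd give a Z-test p-value, corrected
jointly by Benjamini-Hochberg.

The base learners are scikit-learn decision trees; the subsampling scheme,
local-importance accounting and null calibration are implemented here
(scikit-learn exposes neither per-case importance nor without-replacement
out-of-bag bookkeeping).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import config_context
from sklearn.tree import DecisionTreeRegressor

from .diffexp import bh_fdr
from .profiles import MiRProfileMatrix

logger = logging.getLogger(__name__)


@dataclass
class ForestConfig:
    """Forest and null-calibration settings.

    ``n_trees=10000`` and ``n_null=100`` are the full-scale defaults;
    ``mtry`` defaults to ceil(sqrt(n_features)) and ``case_fraction`` to
    2/3 (without replacement) when left as None.
    """

    n_trees: int = 10_000
    mtry: int | None = None
    case_fraction: float = 2.0 / 3.0
    n_null: int = 100
    seed: int = 0

    def validate(self, n_mirs: int) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and not (1 <= self.mtry <= n_mirs):
            raise ValueError("mtry must be in [1, n_mirs]")
        if not 0 < self.case_fraction <= 1:
            raise ValueError("case_fraction must be in (0, 1]")

    def resolved_mtry(self, n_mirs: int) -> int:
        return self.mtry if self.mtry is not None else max(1, math.ceil(math.sqrt(n_mirs)))


@dataclass
class SignificanceResult:
    """Per miR/pathway pair importance calls plus derived summaries."""

    table: pd.DataFrame  # mir, pathway, importance, mu_null, sd_null, z, p, fdr, is_im
    n_excluded: int = 0  # pairs with sd_null == 0, left out of the FDR

    @property
    def significant_pairs(self) -> pd.DataFrame:
        return self.table[self.table["is_im"]]

    @property
    def ims(self) -> set[str]:
        return set(self.significant_pairs["mir"])

    @property
    def significant_pathways(self) -> set[str]:
        return set(self.significant_pairs["pathway"])

    def pathway_counts(self) -> pd.Series:
        """Number of significant pathways per important miR."""
        return self.significant_pairs.groupby("mir").size().sort_values(ascending=False)


def _tree_predict(cl, cr, feat, thr, val, X) -> np.ndarray:
    """Vectorized decision-tree traversal (all rows simultaneously)."""
    node = np.zeros(len(X), dtype=np.int64)
    active = cl[node] >= 0
    while active.any():
        nd = node[active]
        go_left = X[active, feat[nd]] <= thr[nd]
        node[active] = np.where(go_left, cl[nd], cr[nd])
        active = cl[node] >= 0
    return val[node]


def _check_inputs(z: MiRProfileMatrix, nes: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    if z.zscores is None:
        raise ValueError("profile matrix must be Z-normalized first")
    if list(z.zscores.index) != list(nes.index):
        raise ValueError("pathways of the profile matrix and the NES vector must match")
    if len(nes) < 10:
        raise ValueError("need >= 10 pathways")
    y = nes.to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        raise ValueError("enrichment scores are constant; nothing to regress")
    X = np.ascontiguousarray(z.zscores.to_numpy(dtype=np.float32))
    return X, y


def _local_importance(X: np.ndarray, y: np.ndarray, config: ForestConfig, seed_seq: np.random.SeedSequence) -> np.ndarray:
    """Accumulate per-(feature, case) OOB permutation error increases.

    Returns an (n_features, n_cases) matrix of mean error increases over
    the trees in which the case was out-of-bag.
    """
    n_cases, n_feat = X.shape
    mtry = config.resolved_mtry(n_feat)
    n_train = max(1, int(round(config.case_fraction * n_cases)))
    if n_train >= n_cases:
        raise ValueError("case_fraction leaves no out-of-bag cases")
    incr = np.zeros((n_feat, n_cases))
    oob_count = np.zeros(n_cases, dtype=np.int64)
    all_idx = np.arange(n_cases)

    children = seed_seq.spawn(config.n_trees)
    with config_context(assume_finite=True, skip_parameter_validation=True):
        for child in children:
            rng = np.random.default_rng(child)
            train = rng.choice(n_cases, size=n_train, replace=False)
            oob_mask = np.ones(n_cases, dtype=bool)
            oob_mask[train] = False
            oob = all_idx[oob_mask]
            tree = DecisionTreeRegressor(
                max_features=mtry, random_state=int(rng.integers(2**31 - 1))
            )
            tree.fit(X[train], y[train], check_input=False)
            t = tree.tree_
            cl, cr = t.children_left, t.children_right
            feat, thr, val = t.feature, t.threshold, t.value.ravel()
            used = np.unique(feat[feat >= 0])
            n_oob = len(oob)
            oob_count[oob] += 1
            if len(used) == 0:
                continue  # stump: permuting any feature changes nothing
            X_oob = X[oob]
            # one stacked predict: baseline block + one block per used feature
            blocks = np.tile(X_oob, (len(used) + 1, 1))
            for k, m in enumerate(used):
                sl = slice((k + 1) * n_oob, (k + 2) * n_oob)
                blocks[sl, m] = X_oob[rng.permutation(n_oob), m]
            pred = _tree_predict(cl, cr, feat, thr, val, blocks)
            err = (pred - np.tile(y[oob], len(used) + 1)) ** 2
            base = err[:n_oob]
            for k, m in enumerate(used):
                incr[m, oob] += err[(k + 1) * n_oob : (k + 2) * n_oob] - base
    with np.errstate(invalid="ignore", divide="ignore"):
        L = np.where(oob_count > 0, incr / np.maximum(oob_count, 1), 0.0)
    return L


def fit_forest(z: MiRProfileMatrix, nes: pd.Series, config: ForestConfig) -> pd.DataFrame:
    """Local importance matrix L (miRs x pathways) of the forest regression
    of enrichment scores on Z-profiles. Deterministic under a fixed seed."""
    X, y = _check_inputs(z, nes)
    config.validate(X.shape[1])
    L = _local_importance(X, y, config, np.random.SeedSequence(config.seed))
    return pd.DataFrame(L, index=z.mirs, columns=z.pathways)


def permutation_null(
    z: MiRProfileMatrix, nes: pd.Series, config: ForestConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair null mean and sd of local importance.

    Each replicate permutes the enrichment scores across pathways and,
    independently, each miR's Z-profile across pathways, then recomputes
    the full local-importance matrix with a replicate-specific seed.
    """
    if config.n_null < 2:
        raise ValueError("n_null must be >= 2 (sd undefined otherwise)")
    X, y = _check_inputs(z, nes)
    config.validate(X.shape[1])
    n_cases, n_feat = X.shape
    acc = np.zeros((n_feat, n_cases))
    acc2 = np.zeros((n_feat, n_cases))
    for r in range(config.n_null):
        # replicate-specific streams, disjoint from the observed-fit stream
        rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(1, r)))
        y_perm = y[rng.permutation(n_cases)]
        X_perm = np.empty_like(X)
        for m in range(n_feat):
            X_perm[:, m] = X[rng.permutation(n_cases), m]
        L = _local_importance(np.ascontiguousarray(X_perm), y_perm, config, np.random.SeedSequence(entropy=config.seed, spawn_key=(2, r)))
        acc += L
        acc2 += L * L
    mu = acc / config.n_null
    var = (acc2 - config.n_null * mu**2) / (config.n_null - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    return (
        pd.DataFrame(mu, index=z.mirs, columns=z.pathways),
        pd.DataFrame(sd, index=z.mirs, columns=z.pathways),
    )


def call_im_pairs(
    L_obs: pd.DataFrame,
    null_stats: tuple[pd.DataFrame, pd.DataFrame],
    alpha_fdr: float = 0.01,
    two_sided: bool = False,
) -> SignificanceResult:
    """Z-test each miR/pathway pair against its permutation null.

    The default test is one-sided (upper tail): importance is meaningful
    only as an excess over the null. FDR is Benjamini-Hochberg jointly
    across all pairs. Pairs whose null sd is zero cannot be calibrated and
    are excluded (logged).
    """
    mu, sd = null_stats
    for other in (mu, sd):
        if not (L_obs.index.equals(other.index) and L_obs.columns.equals(other.columns)):
            raise ValueError("observed and null matrices must share their index")
    rows = []
    for m in L_obs.index:
        for p in L_obs.columns:
            rows.append((m, p, L_obs.at[m, p], mu.at[m, p], sd.at[m, p]))
    df = pd.DataFrame(rows, columns=["mir", "pathway", "importance", "mu_null", "sd_null"])
    ok = df["sd_null"] > 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("call_im_pairs: excluded %d pairs with zero null sd", n_excluded)
    df = df[ok].reset_index(drop=True)
    if df.empty:
        empty = pd.DataFrame(
            {
                "mir": pd.Series(dtype=str),
                "pathway": pd.Series(dtype=str),
                "importance": pd.Series(dtype=float),
                "mu_null": pd.Series(dtype=float),
                "sd_null": pd.Series(dtype=float),
                "z": pd.Series(dtype=float),
                "p": pd.Series(dtype=float),
                "fdr": pd.Series(dtype=float),
                "is_im": pd.Series(dtype=bool),
            }
        )
        return SignificanceResult(table=empty, n_excluded=n_excluded)
    z = (df["importance"] - df["mu_null"]) / df["sd_null"]
    p = 2 * stats.norm.sf(np.abs(z)) if two_sided else stats.norm.sf(z)
    fdr = bh_fdr(p)
    df = df.assign(z=z, p=p, fdr=fdr, is_im=fdr < alpha_fdr)
    return SignificanceResult(table=df, n_excluded=n_excluded)


def pair_count_distributions(result: SignificanceResult) -> tuple[pd.Series, pd.Series]:
    """(pathways-per-IM counts, IMs-per-pathway counts) over significant
    pairs; both tabulations total the number of significant pairs."""
    sig = result.significant_pairs
    per_mir = sig.groupby("mir").size() if len(sig) else pd.Series(dtype=int)
    per_pathway = sig.groupby("pathway").size() if len(sig) else pd.Series(dtype=int)
    return per_mir, per_pathway
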