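"""Connectome-based predictive modeling (CPM) of grip strength.

The model predicts a phenotype (MVIC, maximum voluntary isometric
contraction) from a subjects x edges fingerprint matrix under leave-one-out
cross-validation.  Within each training fold:

1. covariates (age, sex) are regressed out of the phenotype with an OLS
   model fit on the training subjects only, and the same coefficients are
   applied to the held-out subject (no leakage);
2. features are selected by bootstrap stabilization: in each of ``n_boot``
   iterations a fraction f (drawn uniformly from {0.8, 0.85, 0.9, 0.95}) of
   the training fold is resampled with replacement (floor(f * n) draws) and
   each edge's Pearson correlation with the resampled residualized scores
   is tested at the feature-selection threshold (FST); edges significant in
   at least 80% of iterations are retained, signed by their correlation on
   the full training fold;
3. per subject, the retained positive and negative edges are averaged into
   two strengths; a single-predictor OLS on d = negative - positive
   strength is fit on the training fold and applied to the held-out
   subject.  A fold with no selected edges predicts the training mean and
   is flagged.

Out-of-fold predictions are scored against the fold-residualized observed
scores by Pearson r, prediction R^2 (1 - SSE/SST, which may be negative and
differs from r^2) and RMSE.  Significance comes from a permutation test
that shuffles scores across subjects (covariates stay attached to their
subjects) and reruns the entire procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .fingerprint import FingerprintSet

__all__ = [
    "CPMConfig",
    "CPM",
    "CPMResults",
    "FoldResult",
    "exclude_missing",
    "residualize_scores_fold",
    "edge_correlations",
    "critical_r",
    "bootstrap_select",
    "strengths",
    "fit_predict_fold",
    "loocv_cpm",
    "evaluate_predictions",
    "cpm_permutation",
    "consistent_features",
    "intersect_features",
]


@dataclass(frozen=True)
class CPMConfig:
    """CPM hyperparameters (defaults follow the study protocol)."""

    fst: float = 0.01
    n_boot: int = 1000
    boot_fractions: tuple[float, ...] = (0.8, 0.85, 0.9, 0.95)
    retention: float = 0.80
    covariates: tuple[str, ...] = ("age", "sex")
    n_perm: int = 1000
    seed: int = 0
    with_replacement: bool = True

    def validate(self) -> None:
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie in (0, 1)")
        if not 0 < self.retention <= 1:
            raise ValueError("retention must lie in (0, 1]")
        if any(not 0 < f <= 1 for f in self.boot_fractions):
            raise ValueError("bootstrap fractions must lie in (0, 1]")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


def exclude_missing(
    fingerprints: np.ndarray | FingerprintSet, cohort: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Drop subjects with missing MVIC from both structures (order kept)."""
    values = fingerprints.values if isinstance(fingerprints, FingerprintSet) else np.asarray(fingerprints)
    if values.shape[0] != len(cohort):
        raise ValueError("fingerprints and cohort list different subject counts")
    keep = cohort["mvic"].notna().to_numpy()
    if not keep.any():
        raise ValueError("all subjects have missing scores")
    return values[keep], cohort.loc[keep].reset_index(drop=True)


def residualize_scores_fold(
    train_cov: np.ndarray,
    train_scores: np.ndarray,
    test_cov: np.ndarray,
    test_score: float | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove covariate effects with coefficients estimated on training only."""
    train_cov = np.atleast_2d(np.asarray(train_cov, dtype=float))
    test_cov = np.atleast_2d(np.asarray(test_cov, dtype=float))
    y = np.asarray(train_scores, dtype=float)
    if train_cov.shape[0] != y.size:
        raise ValueError("one covariate row per training subject required")
    X = np.column_stack([np.ones(train_cov.shape[0]), train_cov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("singular covariate design; using least-norm fit")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    train_resid = y - X @ beta
    Xt = np.column_stack([np.ones(test_cov.shape[0]), test_cov])
    test_resid = np.asarray(test_score, dtype=float) - Xt @ beta
    return train_resid, test_resid


def edge_correlations(
    edges: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of every edge with the scores, plus two-sided t-test p.

    Constant edges (or constant scores) have undefined r; they are reported
    as r = NaN with p = 1 so they can never pass a selection threshold.
    """
    edges = np.asarray(edges, dtype=float)
    y = np.asarray(scores, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 subjects for edge correlations")
    xc = edges - edges.mean(axis=0, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        r = np.where(denom > 0, (xc * yc[:, None]).sum(axis=0) / denom, np.nan)
        r = np.clip(r, -1.0, 1.0)
        df = n - 2
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, np.finfo(float).tiny))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isnan(r), 1.0, p)
    return r, p


def critical_r(n: int, alpha: float) -> float:
    """|r| above which the two-sided Pearson t-test p-value is below alpha."""
    df = n - 2
    if df < 1:
        return 1.0
    tc = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(tc / np.sqrt(df + tc**2))


def bootstrap_select(
    train_edges: np.ndarray,
    train_scores: np.ndarray,
    cfg: CPMConfig,
    rng: np.random.Generator,
    max_elements: int = 40_000_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bootstrap-stabilized feature selection on one training fold.

    Returns boolean positive/negative retention masks and the per-edge
    fraction of bootstrap iterations in which it was significant.  Inside
    the loop, ``p < fst`` is evaluated through the exact equivalent
    ``|r| > critical_r(m, fst)``.  Retained sets may be empty; that is a
    legitimate outcome, not an error.
    """
    cfg.validate()
    edges = np.asarray(train_edges, dtype=float)
    y = np.asarray(train_scores, dtype=float)
    n, E = edges.shape
    fractions = np.asarray(cfg.boot_fractions)
    # draw fractions then per-iteration index sets, in iteration order, so
    # the stream is independent of the grouped evaluation below
    fracs = rng.choice(fractions, size=cfg.n_boot)
    sizes = np.floor(fracs * n).astype(int)
    idx_by_iter = [
        rng.integers(0, n, size=m) if cfg.with_replacement
        else rng.permutation(n)[:m]
        for m in sizes
    ]
    counts = np.zeros(E, dtype=np.int64)
    for m in np.unique(sizes):
        group = [idx_by_iter[b] for b in np.flatnonzero(sizes == m)]
        rc = critical_r(m, cfg.fst)
        batch = max(1, int(max_elements // max(m * E, 1)))
        for start in range(0, len(group), batch):
            idx = np.stack(group[start:start + batch])      # (B, m)
            X = edges[idx]                                  # (B, m, E)
            ys = y[idx]                                     # (B, m)
            Xc = X - X.mean(axis=1, keepdims=True)
            yc = ys - ys.mean(axis=1, keepdims=True)
            num = np.einsum("bme,bm->be", Xc, yc)
            den = np.sqrt(np.einsum("bme,bme->be", Xc, Xc)
                          * (yc**2).sum(axis=1)[:, None])
            with np.errstate(invalid="ignore", divide="ignore"):
                r = num / den
            counts += (np.abs(r) > rc).sum(axis=0)  # NaN compares False
    # integer comparison avoids 0.8 * n_boot floating-point edge cases
    need = int(np.ceil(cfg.retention * cfg.n_boot - 1e-9))
    retained = counts >= need
    r_full, _ = edge_correlations(edges, y)
    positive = retained & (r_full > 0)
    negative = retained & (r_full < 0)
    return positive, negative, counts / cfg.n_boot


def strengths(
    edges: np.ndarray, positive: np.ndarray, negative: np.ndarray
) -> tuple[np.ndarray, np.ndarray, dict[str, bool]]:
    """Per-subject mean over the positive and negative edge sets.

    An empty set contributes a strength of 0 for every subject, with a flag.
    """
    edges = np.asarray(edges, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    negative = np.asarray(negative, dtype=bool)
    flags = {"positive_empty": not positive.any(),
             "negative_empty": not negative.any()}
    pos = edges[:, positive].mean(axis=1) if positive.any() else np.zeros(edges.shape[0])
    neg = edges[:, negative].mean(axis=1) if negative.any() else np.zeros(edges.shape[0])
    return pos, neg, flags


def fit_predict_fold(
    train_strength_diff: np.ndarray,
    train_residuals: np.ndarray,
    test_strength_diff: float | np.ndarray,
) -> tuple[np.ndarray, bool]:
    """OLS on d = negative - positive strength; predict the held-out subject.

    A constant predictor (including the no-selected-features case) falls
    back to predicting the training mean; the fold is flagged.
    """
    d = np.asarray(train_strength_diff, dtype=float)
    y = np.asarray(train_residuals, dtype=float)
    dt = np.atleast_1d(np.asarray(test_strength_diff, dtype=float))
    if d.std() == 0:
        return np.full(dt.shape, y.mean()), True
    slope, intercept = np.polyfit(d, y, 1)
    return intercept + slope * dt, False


@dataclass
class FoldResult:
    """Everything computed inside one leave-one-out fold."""

    test_index: int
    cov_beta: np.ndarray
    train_residuals: np.ndarray
    test_residual: float
    positive: np.ndarray        # boolean mask over edges
    negative: np.ndarray
    retention: np.ndarray       # per-edge bootstrap significance fraction
    prediction: float
    empty: bool                 # no features selected in this fold


def _run_fold(
    edges: np.ndarray,
    scores: np.ndarray,
    covariates: np.ndarray,
    test: int,
    cfg: CPMConfig,
    seed: int,
) -> FoldResult:
    n = scores.size
    train = np.setdiff1d(np.arange(n), [test])
    X = np.column_stack([np.ones(train.size), covariates[train]])
    beta, *_ = np.linalg.lstsq(X, scores[train], rcond=None)
    train_resid, test_resid = residualize_scores_fold(
        covariates[train], scores[train], covariates[test], scores[test]
    )
    rng = substream(seed, "fold", test)
    pos, neg, retention = bootstrap_select(edges[train], train_resid, cfg, rng)
    pos_s, neg_s, _ = strengths(edges[train], pos, neg)
    d_train = neg_s - pos_s
    tpos, tneg, _ = strengths(edges[test][None, :], pos, neg)
    d_test = float(tneg[0] - tpos[0])
    pred, empty = fit_predict_fold(d_train, train_resid, d_test)
    return FoldResult(
        test_index=test,
        cov_beta=beta,
        train_residuals=train_resid,
        test_residual=float(np.atleast_1d(test_resid)[0]),
        positive=pos,
        negative=neg,
        retention=retention,
        prediction=float(np.atleast_1d(pred)[0]),
        empty=empty,
    )


def evaluate_predictions(pred: np.ndarray, obs: np.ndarray) -> dict[str, float]:
    """r (with p), prediction R^2 and RMSE of out-of-fold predictions."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.size != obs.size or pred.size < 3:
        raise ValueError("need equal-length prediction/observation vectors (>= 3)")
    sse = float(((obs - pred) ** 2).sum())
    sst = float(((obs - obs.mean()) ** 2).sum())
    rmse = float(np.sqrt(((obs - pred) ** 2).mean()))
    if (pred == pred[0]).all() or (obs == obs[0]).all():
        r, pval = float("nan"), float("nan")
    else:
        r, pval = stats.pearsonr(pred, obs)
    return {
        "r": float(r),
        "r_pvalue": float(pval),
        "r_squared": 1.0 - sse / sst if sst > 0 else float("nan"),
        "rmse": rmse,
    }


def loocv_cpm(
    fingerprints: np.ndarray,
    scores: np.ndarray,
    covariates: np.ndarray,
    cfg: CPMConfig | None = None,
    seed: int | None = None,
) -> "CPMResults":
    """Leave-one-out CPM over all subjects.  Inputs must be complete."""
    cfg = cfg or CPMConfig()
    cfg.validate()
    edges = np.asarray(fingerprints, dtype=float)
    y = np.asarray(scores, dtype=float)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != y.size:
        cov = cov.T
    n = y.size
    if n < 10:
        raise ValueError("CPM needs at least 10 subjects")
    if np.isnan(y).any():
        raise ValueError("scores contain missing values; run exclude_missing first")
    seed = cfg.seed if seed is None else seed
    folds = [_run_fold(edges, y, cov, test, cfg, seed) for test in range(n)]
    pred = np.array([f.prediction for f in folds])
    obs = np.array([f.test_residual for f in folds])
    all_empty = all(f.empty for f in folds)
    if all_empty or (pred == pred[0]).all() or (obs == obs[0]).all():
        metrics = {"r": float("nan"), "r_pvalue": float("nan"),
                   "r_squared": float("nan"), "rmse": float("nan")}
    else:
        metrics = evaluate_predictions(pred, obs)
    cons_pos, cons_neg, mixed = consistent_features(
        [(f.positive, f.negative) for f in folds]
    )
    return CPMResults(
        config=cfg,
        seed=seed,
        predictions=pred,
        observed=obs,
        folds=folds,
        consistent_positive=cons_pos,
        consistent_negative=cons_neg,
        sign_conflicts=mixed,
        metrics=metrics,
        n_empty_folds=sum(f.empty for f in folds),
        all_folds_empty=all_empty,
    )


def consistent_features(
    fold_masks: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Edges selected with the same sign in *every* fold.

    Returns (consistent positive indices, consistent negative indices,
    sign-conflict indices).  An edge selected in every fold but with
    disagreeing signs lands in the conflict set and is excluded from both
    signed sets.
    """
    if not fold_masks:
        raise ValueError("need at least one fold")
    n_folds = len(fold_masks)
    pos_counts = np.sum([p for p, _ in fold_masks], axis=0)
    neg_counts = np.sum([n for _, n in fold_masks], axis=0)
    cons_pos = np.flatnonzero(pos_counts == n_folds)
    cons_neg = np.flatnonzero(neg_counts == n_folds)
    mixed = np.flatnonzero(
        (pos_counts + neg_counts == n_folds) & (pos_counts > 0) & (neg_counts > 0)
    )
    return cons_pos, cons_neg, mixed


def intersect_features(
    sets_a: tuple[np.ndarray, np.ndarray],
    sets_b: tuple[np.ndarray, np.ndarray],
    n_edges: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Edges present with the same sign in both tasks' consistent sets."""
    pos = np.intersect1d(sets_a[0], sets_b[0])
    neg = np.intersect1d(sets_a[1], sets_b[1])
    if n_edges is not None:
        for arr in (*sets_a, *sets_b):
            if np.any(np.asarray(arr) >= n_edges):
                raise ValueError("edge index exceeds the stated edge count")
    return pos, neg


def cpm_permutation(
    fingerprints: np.ndarray,
    scores: np.ndarray,
    covariates: np.ndarray,
    cfg: CPMConfig | None = None,
    observed_r: float | None = None,
    n_perm: int | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, float, int]:
    """Permutation null for the CPM prediction correlation.

    Each permutation shuffles the scores across subjects (covariates stay
    with their subjects) and reruns the full leave-one-out procedure —
    covariate removal, bootstrap selection and prediction — recording the
    prediction r.  Permutations in which every fold selects no features
    yield r = NaN and are excluded from the null (their count is returned).
    The p-value uses the add-one estimator over valid permutations.
    """
    cfg = cfg or CPMConfig()
    n_perm = cfg.n_perm if n_perm is None else n_perm
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    seed = cfg.seed if seed is None else seed
    y = np.asarray(scores, dtype=float)
    if observed_r is None:
        observed_r = loocv_cpm(fingerprints, y, covariates, cfg, seed=seed).metrics["r"]
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = substream(seed, "perm-shuffle", k).permutation(y.size)
        res = loocv_cpm(fingerprints, y[perm], covariates, cfg,
                        seed=_perm_seed(seed, k))
        null[k] = res.metrics["r"]
    valid = null[~np.isnan(null)]
    n_invalid = int(np.isnan(null).sum())
    if valid.size == 0:
        raise RuntimeError(
            f"no valid permutations at FST={cfg.fst}: every permuted fold "
            "selected no features"
        )
    pval = (1.0 + np.count_nonzero(valid >= observed_r)) / (valid.size + 1.0)
    return null, float(pval), n_invalid


def _perm_seed(seed: int, k: int) -> int:
    from ._rng import child_seed

    return child_seed(seed, "perm-run", k)


@dataclass
class CPMResults:
    """Results of a leave-one-out CPM fit."""

    config: CPMConfig
    seed: int
    predictions: np.ndarray
    observed: np.ndarray
    folds: list[FoldResult]
    consistent_positive: np.ndarray
    consistent_negative: np.ndarray
    sign_conflicts: np.ndarray
    metrics: dict[str, float]
    n_empty_folds: int
    all_folds_empty: bool
    permutation_null: np.ndarray | None = None
    permutation_p: float | None = None
    permutation_invalid: int | None = None
    _model: "CPM | None" = field(default=None, repr=False)

    @property
    def fold_features(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per fold, (positive, negative) selected edge indices."""
        return [(np.flatnonzero(f.positive), np.flatnonzero(f.negative))
                for f in self.folds]

    def permutation_test(self, n_perm: int | None = None,
                         seed: int | None = None) -> tuple[np.ndarray, float]:
        if self._model is None:
            raise RuntimeError("results are detached from their model")
        null, pval, n_invalid = cpm_permutation(
            self._model.edges, self._model.scores, self._model.covariates,
            self.config, observed_r=self.metrics["r"], n_perm=n_perm,
            seed=self.seed if seed is None else seed,
        )
        self.permutation_null = null
        self.permutation_p = pval
        self.permutation_invalid = n_invalid
        return null, pval

    def summary(self) -> str:
        m = self.metrics
        lines = [
            "Connectome-based predictive model (leave-one-out)",
            "=" * 50,
            f"subjects                      {self.predictions.size:>10d}",
            f"feature selection threshold   {self.config.fst:>10g}",
            f"bootstrap iterations          {self.config.n_boot:>10d}",
            f"prediction r                  {m['r']:>10.3f}",
            f"r p-value                     {m['r_pvalue']:>10.4g}",
            f"prediction R^2                {m['r_squared']:>10.3f}",
            f"RMSE                          {m['rmse']:>10.2f}",
            f"consistent negative edges     {self.consistent_negative.size:>10d}",
            f"consistent positive edges     {self.consistent_positive.size:>10d}",
            f"empty folds                   {self.n_empty_folds:>10d}",
        ]
        if self.permutation_p is not None:
            lines.append(f"permutation p                 {self.permutation_p:>10.4g}")
        return "\n".join(lines)


class CPM:
    """Connectome-based predictive model of a phenotype.

    Parameters
    ----------
    edges
        Subjects x edges Fisher-z fingerprint matrix (complete cases).
    scores
        Phenotype vector (no missing values; use :meth:`from_dataframe` or
        :func:`exclude_missing` to drop subjects with missing scores).
    covariates
        Subjects x K covariate matrix (default columns: age, sex).
    """

    def __init__(self, edges: np.ndarray, scores: np.ndarray,
                 covariates: np.ndarray, subject_ids: list[str] | None = None,
                 config: CPMConfig | None = None):
        self.edges = np.asarray(edges, dtype=float)
        self.scores = np.asarray(scores, dtype=float)
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        self.covariates = cov.T if cov.shape[0] != self.scores.size else cov
        self.subject_ids = subject_ids
        self.config = config or CPMConfig()

    @classmethod
    def from_dataframe(
        cls,
        fingerprints: FingerprintSet | np.ndarray,
        cohort: pd.DataFrame,
        score_col: str = "mvic",
        covariate_cols: tuple[str, ...] | None = None,
        config: CPMConfig | None = None,
    ) -> "CPM":
        """Build from a fingerprint matrix and a cohort table.

        Subjects with a missing score are excluded from both inputs (the
        study drops 3 of 55 this way, leaving 52).
        """
        config = config or CPMConfig()
        covariate_cols = covariate_cols or config.covariates
        cohort = cohort.rename(columns={score_col: "mvic"}) if score_col != "mvic" else cohort
        values, kept = exclude_missing(fingerprints, cohort)
        return cls(
            edges=values,
            scores=kept["mvic"].to_numpy(dtype=float),
            covariates=kept[list(covariate_cols)].to_numpy(dtype=float),
            subject_ids=kept["subject_id"].tolist() if "subject_id" in kept else None,
            config=config,
        )

    def fit(self, seed: int | None = None) -> CPMResults:
        results = loocv_cpm(self.edges, self.scores, self.covariates,
                            self.config, seed=seed)
        results._model = self
        return results
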