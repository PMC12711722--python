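"""Cross-session connectome identification and the differential power statistic.

Identification treats each subject's session-A edge vector as a database
entry and asks whether the session-B vector of the same subject is its
nearest neighbour under Pearson correlation.  The identification matrix M
has M[i, j] = corr(B_i, A_j); a row (column) scores a hit when its diagonal
entry is the strict maximum.  Chance level is assessed by permuting the
subject correspondence between sessions.

Differential power (DP) scores how much each edge contributes to
identification.  For edge e with session-A values a and session-B values v,
the feature product value of subjects (i, j) is a_i * v_j.  A
discriminative edge has a_i * v_i larger than cross-subject products, so we
count violations

    V_i(e) = #{j != i : a_i v_j >= a_i v_i} + #{j != i : a_j v_i >= a_i v_i}

turn them into empirical probabilities p_{e,i} = max(V_i(e), 1) / (2(N-1))
(flooring at one violation keeps -ln finite without reordering edges), and
sum DP(e) = sum_i -ln p_{e,i}.  High DP means low violation probability,
i.e. a subject-specific edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .connectome import edge_pairs
from .parcellation import Parcellation

__all__ = [
    "FingerprintSet",
    "IdentificationResult",
    "Identification",
    "DPResult",
    "identification_matrix",
    "identification_accuracy",
    "identification_permutation",
    "residualize_confounds",
    "differential_power",
    "dp_threshold_mask",
    "node_counts",
    "network_fractions",
]


@dataclass
class FingerprintSet:
    """Subjects x edges fingerprint matrix for one session/task."""

    values: np.ndarray
    subject_ids: list[str] | None = None
    session_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("fingerprints must be a subjects x edges matrix")
        if self.subject_ids is None:
            self.subject_ids = [f"sub-{k + 1:03d}" for k in range(self.values.shape[0])]
        self.subject_ids = [str(s) for s in self.subject_ids]
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("one subject id per fingerprint row required")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject ids must be unique")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]


def _check_aligned(set_a: FingerprintSet, set_b: FingerprintSet) -> None:
    if set_a.subject_ids != set_b.subject_ids:
        raise ValueError("fingerprint sets are not aligned on the same subjects")
    if set_a.n_edges != set_b.n_edges:
        raise ValueError("fingerprint sets have different edge counts")


def identification_matrix(set_a: FingerprintSet, set_b: FingerprintSet) -> np.ndarray:
    """N x N Pearson correlations; rows are set-B subjects, columns set-A."""
    _check_aligned(set_a, set_b)
    a = _standardize_rows(set_a.values)
    b = _standardize_rows(set_b.values)
    m = (b @ a.T) / set_a.n_edges
    return np.clip(m, -1.0, 1.0)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant fingerprint row(s); correlation undefined")
    return x / sd


def identification_accuracy(
    id_matrix: np.ndarray,
) -> tuple[float, float, dict[str, np.ndarray]]:
    """Row-wise and column-wise identification accuracy.

    A row (column) is a hit when its diagonal entry strictly exceeds every
    off-diagonal entry; exact ties count as misses.
    """
    m = np.asarray(id_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("identification matrix must be square")
    diag = np.diag(m)
    off = m.copy()
    np.fill_diagonal(off, -np.inf)
    row_hits = diag > off.max(axis=1)
    col_hits = diag > off.max(axis=0)
    hits = {"rowwise": row_hits, "columnwise": col_hits}
    return float(row_hits.mean()), float(col_hits.mean()), hits


def identification_permutation(
    set_a: FingerprintSet,
    set_b: FingerprintSet,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Permutation null for identification accuracy.

    Each permutation shuffles the subject correspondence between the two
    sessions and records the mean of the two directional accuracies.  The
    p-value uses the add-one estimator (1 + #{null >= observed}) /
    (n_perm + 1), so it is never exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    m = identification_matrix(set_a, set_b)
    row_acc, col_acc, _ = identification_accuracy(m)
    observed = (row_acc + col_acc) / 2.0
    rng = substream(seed, "ident-perm")
    null = np.empty(n_perm)
    n = m.shape[0]
    for p in range(n_perm):
        perm = rng.permutation(n)
        r, c, _ = identification_accuracy(m[:, perm])
        null[p] = (r + c) / 2.0
    pval = (1.0 + np.count_nonzero(null >= observed)) / (n_perm + 1.0)
    return null, float(pval)


def residualize_confounds(
    set_a: FingerprintSet,
    set_b: FingerprintSet,
    confounds: pd.DataFrame | np.ndarray,
) -> tuple[FingerprintSet, FingerprintSet]:
    """Regress subject-level confounds out of every edge, per session.

    ``confounds`` holds one row per subject (e.g. session order, motion
    outlier count, total brain volume).  Each edge is replaced by its OLS
    residual on [intercept, confounds] across subjects, independently for
    the two sets.
    """
    _check_aligned(set_a, set_b)
    if isinstance(confounds, pd.DataFrame):
        bad = confounds.index[confounds.isna().any(axis=1)].tolist()
        if bad:
            raise ValueError(f"missing confound values for subjects {bad}")
        conf = confounds.to_numpy(dtype=float)
    else:
        conf = np.asarray(confounds, dtype=float)
        if conf.ndim == 1:
            conf = conf[:, None]
        if np.isnan(conf).any():
            rows = np.flatnonzero(np.isnan(conf).any(axis=1)).tolist()
            raise ValueError(f"missing confound values for subjects {rows}")
    if conf.shape[0] != set_a.n_subjects:
        raise ValueError("one confound row per subject required")
    X = np.column_stack([np.ones(conf.shape[0]), conf])

    def _resid(values: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(X, values, rcond=None)
        return values - X @ beta

    return (
        FingerprintSet(_resid(set_a.values), list(set_a.subject_ids),
                       set_a.session_label),
        FingerprintSet(_resid(set_b.values), list(set_b.subject_ids),
                       set_b.session_label),
    )


@dataclass
class DPResult:
    """Differential power per edge plus per-subject violation probabilities."""

    dp: np.ndarray          # (E,) nonnegative
    pe_matrix: np.ndarray   # (N, E) in (0, 1]

    def threshold_mask(self, percentile: float = 99.5) -> np.ndarray:
        return dp_threshold_mask(self.dp, percentile)


def differential_power(set_a: FingerprintSet, set_b: FingerprintSet,
                       chunk: int = 512) -> DPResult:
    """Compute DP for every edge (vectorized, chunked over edges)."""
    _check_aligned(set_a, set_b)
    a_all, v_all = set_a.values, set_b.values
    n = set_a.n_subjects
    if n < 3:
        raise ValueError("differential power needs at least 3 subjects")
    E = set_a.n_edges
    dp = np.empty(E)
    pe = np.empty((n, E))
    denom = 2.0 * (n - 1)
    for start in range(0, E, chunk):
        sl = slice(start, min(start + chunk, E))
        a = a_all[:, sl]          # (N, c)
        v = v_all[:, sl]
        within = a * v            # (N, c) within-subject products
        # cross1[i, j] = a_i * v_j ; cross2[i, j] = a_j * v_i
        cross1 = a[:, None, :] * v[None, :, :]
        viol1 = (cross1 >= within[:, None, :]).sum(axis=1) - 1  # j = i always >=
        viol2 = (cross1 >= within[None, :, :]).sum(axis=0) - 1
        v_count = viol1 + viol2
        p = np.maximum(v_count, 1) / denom
        pe[:, sl] = p
        dp[sl] = -np.log(p).sum(axis=0)
    return DPResult(dp=dp, pe_matrix=pe)


def dp_threshold_mask(dp: np.ndarray, percentile: float = 99.5) -> np.ndarray:
    """Edges with DP strictly above the given linear-interpolation percentile."""
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    dp = np.asarray(dp, dtype=float)
    threshold = np.percentile(dp, percentile, method="linear")
    return dp > threshold


def node_counts(
    mask: np.ndarray,
    parcellation: Parcellation,
    top_fraction: float = 0.03,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-ROI count of suprathreshold incident edges plus the top node set.

    The top set takes ``ceil(top_fraction * R)`` ROIs ranked by count
    (descending), ties broken by ascending ROI id.
    """
    mask = np.asarray(mask, dtype=bool)
    R = parcellation.n_rois
    rows, cols = edge_pairs(R)
    if mask.size != rows.size:
        raise ValueError("mask length inconsistent with the parcellation")
    counts = np.bincount(rows[mask], minlength=R) + np.bincount(cols[mask], minlength=R)
    table = pd.DataFrame({
        "roi_id": parcellation.roi_ids,
        "network": parcellation.network_labels,
        "count": counts,
    })
    n_top = int(np.ceil(top_fraction * R))
    order = np.lexsort((parcellation.roi_ids, -counts))
    top = parcellation.roi_ids[order[:n_top]]
    return table, np.asarray(top)


def network_fractions(mask: np.ndarray, parcellation: Parcellation) -> pd.DataFrame:
    """Fraction of suprathreshold edges joining each network pair.

    Returns a symmetric networks x networks table; entries over unordered
    pairs (upper triangle including the diagonal) sum to 1.
    """
    mask = np.asarray(mask, dtype=bool)
    total = int(mask.sum())
    if total == 0:
        raise ValueError("empty suprathreshold mask")
    codes = parcellation.network_codes()
    rows, cols = edge_pairs(parcellation.n_rois)
    if mask.size != rows.size:
        raise ValueError("mask length inconsistent with the parcellation")
    K = parcellation.n_networks
    counts = np.zeros((K, K))
    p = codes[rows[mask]]
    q = codes[cols[mask]]
    lo, hi = np.minimum(p, q), np.maximum(p, q)
    np.add.at(counts, (lo, hi), 1)
    frac = counts / total
    frac = frac + np.triu(frac, 1).T  # mirror to a symmetric matrix
    names = list(parcellation.network_names)
    return pd.DataFrame(frac, index=names, columns=names)


@dataclass
class IdentificationResult:
    """Identification matrix, per-direction accuracies and optional null."""

    id_matrix: np.ndarray
    accuracy_rowwise: float
    accuracy_columnwise: float
    hits: dict[str, np.ndarray]
    session_labels: tuple[str, str] = ("", "")
    permutation_null: np.ndarray | None = None
    permutation_p: float | None = None

    @property
    def accuracy(self) -> float:
        """Mean of the two directional accuracies."""
        return (self.accuracy_rowwise + self.accuracy_columnwise) / 2.0

    def summary(self) -> str:
        lines = [
            "Connectome identification",
            "=" * 41,
            f"subjects                 {self.id_matrix.shape[0]:>10d}",
            f"accuracy ({self.session_labels[1] or 'B'} rows)      "
            f"{self.accuracy_rowwise:>10.3f}",
            f"accuracy ({self.session_labels[0] or 'A'} columns)   "
            f"{self.accuracy_columnwise:>10.3f}",
        ]
        if self.permutation_p is not None:
            lines.append(f"permutation null mean    {self.permutation_null.mean():>10.4f}")
            lines.append(f"permutation p            {self.permutation_p:>10.4g}")
        return "\n".join(lines)


class Identification:
    """Cross-session identification model over two aligned fingerprint sets.

    Parameters
    ----------
    set_a, set_b
        Aligned :class:`FingerprintSet` objects (e.g. auditory- and
        visual-task sessions).
    confounds
        Optional subject-level confound table; when given, every edge is
        residualized on the confounds (per set) before identification.
    """

    def __init__(self, set_a: FingerprintSet, set_b: FingerprintSet,
                 confounds: pd.DataFrame | np.ndarray | None = None):
        _check_aligned(set_a, set_b)
        if confounds is not None:
            set_a, set_b = residualize_confounds(set_a, set_b, confounds)
        self.set_a = set_a
        self.set_b = set_b

    def fit(self, n_perm: int = 0, seed: int = 0) -> IdentificationResult:
        m = identification_matrix(self.set_a, self.set_b)
        row_acc, col_acc, hits = identification_accuracy(m)
        result = IdentificationResult(
            id_matrix=m,
            accuracy_rowwise=row_acc,
            accuracy_columnwise=col_acc,
            hits=hits,
            session_labels=(self.set_a.session_label, self.set_b.session_label),
        )
        if n_perm:
            null, pval = identification_permutation(self.set_a, self.set_b,
                                                    n_perm=n_perm, seed=seed)
            result.permutation_null = null
            result.permutation_p = pval
        return result

    def differential_power(self) -> DPResult:
        return differential_power(self.set_a, self.set_b)
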