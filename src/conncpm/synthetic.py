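"""Synthetic cohorts with the statistical structure the analyses assume.

The generative model is additive on Fisher-z edges.  For subject s, session
k (k = 0, 1) and edge e,

    z[e, s, k] = mu[e] + u[e, s] + w[e, s, k] + n[e, s, k]

with a group mean ``mu`` elevated for within-network edges, a
subject-specific effect ``u ~ N(0, sigma_subject^2)`` shared across
sessions (the "fingerprint"), a session-specific effect
``w ~ N(0, sigma_session^2)`` and optional residual edge noise ``n``.  All
effects are independent across subjects, sessions and edges.

The phenotype (MVIC, maximum voluntary isometric contraction — grip
strength in arbitrary dynamometer units) is driven by a small planted set
P of edges with strictly negative weights gamma[e], emulating the
negative-network character of connectome predictors of strength:

    mvic[s] = beta0 + beta_age * age[s] + beta_sex * sex[s]
              + sum_{e in P} gamma[e] * u[e, s] + eps[s]

A configurable number of subjects (default 3 of 55) have missing MVIC.
Time series consistent with a session's edge vector are produced by
projecting the implied correlation matrix to the nearest feasible
correlation matrix and coloring white Gaussian noise with its Cholesky
factor, then adding known trend, above-cutoff and nuisance components that
the connectome pipeline is expected to remove.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .connectome import RunTimeSeries, edge_pairs, n_edges
from .parcellation import (
    DEFAULT_NETWORK_NAMES,
    DEFAULT_NETWORK_SIZES,
    Parcellation,
    make_parcellation,
)

__all__ = [
    "SynthConfig",
    "LatentCohort",
    "Parcellation",
    "make_parcellation",
    "sample_latent_cohort",
    "generate_scores",
    "simulate_cohort",
    "target_correlation",
    "generate_run_timeseries",
    "simulate_session_runs",
]

COHORT_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "mvic",
    "motion_outliers",
    "brain_volume",
    "session_order",
)


@dataclass(frozen=True)
class SynthConfig:
    """Synthetic-cohort configuration; defaults emulate the study conditions.

    55 older adults (29 female), ages uniform on 65-87, two task sessions of
    five 245-timepoint runs at TR = 1.75 s, 215 ROIs in seven networks.
    Edge-effect scales (``sigma_subject`` = 0.4 vs ``sigma_session`` = 0.1)
    put subject identity well above session variability, matching the
    perfect-identification regime.  Phenotype effects place male mean MVIC
    ~12,500 units above female and a weak negative age slope; six planted
    within-SC edges carry negative weights of magnitude ~6,000 so the edge
    signal is strong but not dominant relative to ``sigma_score``.
    """

    n_subjects: int = 55
    n_rois: int = 215
    network_sizes: tuple[int, ...] | None = None
    n_runs: int = 5
    n_timepoints_per_run: int = 245
    tr_seconds: float = 1.75
    # latent edge model
    mu_between: float = 0.05
    mu_within: float = 0.30
    sigma_subject: float = 0.4
    sigma_session: float = 0.1
    sigma_edge_noise: float = 0.0
    # planted phenotype edges
    planted_edge_count: int = 6
    planted_network: str = "SC"
    planted_weight_mean: float = 6000.0
    planted_weight_sd: float = 600.0
    planted_positive: bool = False
    # phenotype model
    beta0: float = 29200.0
    beta_age: float = -100.0
    beta_sex: float = 12500.0
    sigma_score: float = 1500.0
    n_missing_scores: int = 3
    age_range: tuple[float, float] = (65.0, 87.0)
    n_female: int | None = None
    # time-series artifacts (amplitudes relative to unit-variance signal)
    trend_amp: float = 0.5
    highfreq_amp: float = 0.3
    confound_amp: float = 0.5
    # null-confound switch: > 0 couples edges to brain volume
    confound_edge_coupling: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "n_rois": self.n_rois,
            "n_runs": self.n_runs,
            "n_timepoints_per_run": self.n_timepoints_per_run,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sigma_subject", "sigma_session", "sigma_edge_noise",
                     "planted_weight_sd", "sigma_score"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.n_missing_scores < self.n_subjects:
            raise ValueError("n_missing_scores must be < n_subjects")
        if self.planted_edge_count < 0:
            raise ValueError("planted_edge_count must be >= 0")
        if self.planted_edge_count > n_edges(self.n_rois):
            raise ValueError("planted_edge_count exceeds the number of edges")

    def parcellation(self) -> Parcellation:
        return make_parcellation(self.n_rois, self.network_sizes)


@dataclass
class LatentCohort:
    """Ground truth for one synthetic cohort."""

    config: SynthConfig
    parcellation: Parcellation
    mean_edges: np.ndarray              # (E,)
    subject_effects: np.ndarray         # (S, E)
    session_edges: list[np.ndarray]     # two (S, E) matrices
    planted_edges: np.ndarray           # (P,) canonical edge indices
    planted_weights: np.ndarray         # (P,) strictly negative by default
    cohort: pd.DataFrame                # COHORT_COLUMNS

    @property
    def n_subjects(self) -> int:
        return self.subject_effects.shape[0]

    @property
    def n_edges(self) -> int:
        return self.subject_effects.shape[1]

    def fingerprint_matrix(self, session: int) -> np.ndarray:
        """Subjects x edges latent fingerprint matrix for ``session``."""
        return self.session_edges[session]


def sample_latent_cohort(parcellation: Parcellation | None = None,
                         cfg: SynthConfig | None = None,
                         seed: int | None = None) -> LatentCohort:
    """Draw latent edges, planted phenotype edges and demographics.

    The returned cohort table has MVIC unset (NaN); :func:`generate_scores`
    fills it.  Deterministic given (cfg, seed): named substreams keep each
    component reproducible independently of the others.
    """
    cfg = cfg or SynthConfig()
    cfg.validate()
    if parcellation is None:
        parcellation = cfg.parcellation()
    if parcellation.n_rois != cfg.n_rois:
        raise ValueError("parcellation size does not match cfg.n_rois")
    seed = cfg.seed if seed is None else seed
    S, E = cfg.n_subjects, n_edges(cfg.n_rois)

    mean_edges = _mean_edges(parcellation, cfg)
    rng = substream(seed, "latent-edges")
    u = rng.normal(0.0, cfg.sigma_subject, size=(S, E))
    sessions = []
    for k in range(2):
        w = rng.normal(0.0, cfg.sigma_session, size=(S, E))
        z = mean_edges[None, :] + u + w
        if cfg.sigma_edge_noise > 0:
            z = z + rng.normal(0.0, cfg.sigma_edge_noise, size=(S, E))
        sessions.append(z)

    planted, weights = _plant_edges(parcellation, cfg, substream(seed, "planted"))
    cohort = _demographics(cfg, substream(seed, "demographics"))

    if cfg.confound_edge_coupling > 0:
        bv = cohort["brain_volume"].to_numpy()
        bv = (bv - bv.mean()) / bv.std()
        load = substream(seed, "confound-coupling").normal(0.0, 1.0, size=E)
        for z in sessions:
            z += cfg.confound_edge_coupling * bv[:, None] * load[None, :]

    return LatentCohort(
        config=cfg,
        parcellation=parcellation,
        mean_edges=mean_edges,
        subject_effects=u,
        session_edges=sessions,
        planted_edges=planted,
        planted_weights=weights,
        cohort=cohort,
    )


def _mean_edges(parcellation: Parcellation, cfg: SynthConfig) -> np.ndarray:
    codes = parcellation.network_codes()
    rows, cols = edge_pairs(parcellation.n_rois)
    within = codes[rows] == codes[cols]
    return np.where(within, cfg.mu_within, cfg.mu_between)


def _plant_edges(parcellation: Parcellation, cfg: SynthConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    P = cfg.planted_edge_count
    if P == 0:
        return np.empty(0, dtype=np.intp), np.empty(0)
    codes = parcellation.network_codes()
    rows, cols = edge_pairs(parcellation.n_rois)
    try:
        target = list(parcellation.network_names).index(cfg.planted_network)
        pool = np.flatnonzero((codes[rows] == target) & (codes[cols] == target))
    except ValueError:
        pool = np.empty(0, dtype=np.intp)
    if pool.size >= P:
        planted = rng.choice(pool, size=P, replace=False)
    else:  # top up from the remaining edges, still without replacement
        rest = np.setdiff1d(np.arange(rows.size), pool)
        extra = rng.choice(rest, size=P - pool.size, replace=False)
        planted = np.concatenate([pool, extra])
    planted = np.sort(planted.astype(np.intp))
    magnitudes = np.abs(rng.normal(cfg.planted_weight_mean,
                                   cfg.planted_weight_sd, size=P))
    magnitudes = np.maximum(magnitudes, 1e-9 * max(cfg.planted_weight_mean, 1.0))
    weights = magnitudes if cfg.planted_positive else -magnitudes
    return planted, weights


def _demographics(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    S = cfg.n_subjects
    n_female = cfg.n_female
    if n_female is None:
        n_female = int(round(S * 29 / 55))  # study sex ratio
    sex = np.concatenate([np.zeros(n_female, dtype=int),
                          np.ones(S - n_female, dtype=int)])
    rng.shuffle(sex)
    order = np.concatenate([np.zeros(S // 2, dtype=int),
                            np.ones(S - S // 2, dtype=int)])
    rng.shuffle(order)
    return pd.DataFrame({
        "subject_id": [f"sub-{k + 1:03d}" for k in range(S)],
        "age": rng.uniform(*cfg.age_range, size=S),
        "sex": sex,
        "mvic": np.full(S, np.nan),
        "motion_outliers": rng.poisson(40.0, size=S),
        "brain_volume": rng.normal(1.25e6, 1.0e5, size=S),
        "session_order": order,
    })


def generate_scores(latent: LatentCohort, cfg: SynthConfig | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Fill MVIC: covariate effects + planted edge signal + noise + missingness.

    Exactly ``cfg.n_missing_scores`` subjects receive a missing (NaN) MVIC.
    """
    cfg = cfg or latent.config
    cfg.validate()
    seed = cfg.seed if seed is None else seed
    rng = substream(seed, "scores")
    cohort = latent.cohort.copy()
    S = len(cohort)
    edge_signal = latent.subject_effects[:, latent.planted_edges] @ latent.planted_weights
    mvic = (
        cfg.beta0
        + cfg.beta_age * cohort["age"].to_numpy()
        + cfg.beta_sex * cohort["sex"].to_numpy()
        + edge_signal
        + rng.normal(0.0, cfg.sigma_score, size=S)
    )
    if cfg.n_missing_scores:
        missing = rng.choice(S, size=cfg.n_missing_scores, replace=False)
        mvic[missing] = np.nan
    cohort["mvic"] = mvic
    return cohort


def simulate_cohort(cfg: SynthConfig | None = None,
                    seed: int | None = None) -> LatentCohort:
    """Sample a complete cohort (latent edges + scored cohort table)."""
    cfg = cfg or SynthConfig()
    latent = sample_latent_cohort(cfg=cfg, seed=seed)
    latent.cohort = generate_scores(latent, cfg, seed=seed)
    return latent


def target_correlation(edge_vector: np.ndarray, n_rois: int,
                       floor: float = 1e-4, max_iter: int = 10) -> np.ndarray:
    """Correlation matrix implied by a Fisher-z edge vector.

    Applies the inverse Fisher transform, symmetrizes with a unit diagonal
    and repairs indefiniteness by eigenvalue clipping at ``floor`` followed
    by re-normalization to a unit diagonal.  Because re-normalization can
    push the smallest eigenvalue back below the floor, the clip/renormalize
    pass is iterated a few times and finished with a shrink-toward-identity
    step ``(1 - a) M + a I`` (which keeps the unit diagonal) so the output
    always satisfies ``lambda_min >= floor``.  For edge vectors already
    consistent with a valid correlation matrix the function is the
    identity.
    """
    edge_vector = np.asarray(edge_vector, dtype=float)
    if not np.all(np.isfinite(edge_vector)):
        raise ValueError("edge vector contains non-finite entries")
    if edge_vector.size != n_edges(n_rois):
        raise ValueError("edge vector length does not match n_rois")
    r = np.tanh(edge_vector)
    mat = np.eye(n_rois)
    rows, cols = edge_pairs(n_rois)
    mat[rows, cols] = r
    mat[cols, rows] = r
    for _ in range(max_iter):
        vals, vecs = np.linalg.eigh(mat)
        if vals[0] >= floor:
            return mat
        mat = (vecs * np.maximum(vals, floor)) @ vecs.T
        d = np.sqrt(np.diag(mat))
        mat = mat / np.outer(d, d)
        mat = (mat + mat.T) / 2.0
        np.fill_diagonal(mat, 1.0)
    lam_min = float(np.linalg.eigvalsh(mat)[0])
    if lam_min < floor:
        a = (floor - lam_min) / (1.0 - lam_min)
        mat = (1.0 - a) * mat + a * np.eye(n_rois)
    return mat


def generate_run_timeseries(
    target: np.ndarray,
    cfg: SynthConfig | None = None,
    confound_loadings: np.ndarray | None = None,
    seed: int | None = None,
) -> list[RunTimeSeries]:
    """Simulate the session's runs with population correlation ``target``.

    Each run draws i.i.d. Gaussian vectors colored by the Cholesky factor of
    ``target``, then adds (i) a per-ROI linear trend, (ii) low-amplitude
    sinusoids above the 0.2 Hz cutoff and (iii) known linear combinations of
    nine nuisance regressors (six motion-like random walks plus AR(1)
    white-matter-, CSF- and global-mean-like series).  All nuisance
    regressors are attached to the returned runs so preprocessing can
    regress them out exactly.
    """
    cfg = cfg or SynthConfig()
    target = np.asarray(target, dtype=float)
    R = target.shape[0]
    try:
        chol = np.linalg.cholesky(target)
    except np.linalg.LinAlgError as exc:
        raise ValueError("target correlation matrix is not positive definite") from exc
    seed = cfg.seed if seed is None else seed
    rng = substream(seed, "timeseries")
    T = cfg.n_timepoints_per_run
    nyquist = 0.5 / cfg.tr_seconds
    t = np.arange(T, dtype=float)
    if confound_loadings is not None:
        confound_loadings = np.asarray(confound_loadings, dtype=float)
        if confound_loadings.shape != (9, R):
            raise ValueError("confound_loadings must have shape (9, n_rois)")
    runs: list[RunTimeSeries] = []
    for k in range(cfg.n_runs):
        data = rng.standard_normal((T, R)) @ chol.T
        # (i) linear trend
        slopes = rng.normal(0.0, cfg.trend_amp, size=R)
        data += np.linspace(-0.5, 0.5, T)[:, None] * slopes[None, :]
        # (ii) above-cutoff sinusoids (only meaningful if the band is open)
        if cfg.highfreq_amp > 0 and nyquist > 0.25:
            freqs = rng.uniform(0.25, 0.98 * nyquist, size=R)
            phases = rng.uniform(0.0, 2 * np.pi, size=R)
            data += cfg.highfreq_amp * np.sin(
                2 * np.pi * freqs[None, :] * t[:, None] * cfg.tr_seconds
                + phases[None, :]
            )
        # (iii) nuisance contamination with known loadings
        nuis = _nuisance_regressors(rng, T)
        load = (confound_loadings if confound_loadings is not None
                else rng.normal(0.0, cfg.confound_amp, size=(9, R)))
        data += nuis @ load
        runs.append(RunTimeSeries(data=data, tr_seconds=cfg.tr_seconds,
                                  run_index=k, nuisance=nuis))
    return runs


def _nuisance_regressors(rng: np.random.Generator, T: int) -> np.ndarray:
    """Nine regressors: 6 motion-like random walks + 3 AR(1) tissue means."""
    cols = []
    for _ in range(6):
        walk = np.cumsum(rng.standard_normal(T))
        cols.append(_standardize(walk))
    for _ in range(3):
        eps = rng.standard_normal(T)
        ar = np.empty(T)
        ar[0] = eps[0]
        for i in range(1, T):
            ar[i] = 0.9 * ar[i - 1] + eps[i]
        cols.append(_standardize(ar))
    return np.column_stack(cols)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def simulate_session_runs(latent: LatentCohort, subject: int, session: int,
                          seed: int | None = None) -> list[RunTimeSeries]:
    """Runs for one subject/session, seeded by (cohort seed, subject, session)."""
    cfg = latent.config
    seed = cfg.seed if seed is None else seed
    from ._rng import child_seed

    target = target_correlation(latent.session_edges[session][subject], cfg.n_rois)
    return generate_run_timeseries(
        target, cfg, seed=child_seed(seed, "runs", subject, session)
    )
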