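import numpy as np
import pytest

from conncpm.synthetic import SynthConfig, simulate_cohort


def realized_planted_correlations(latent):
    """Sample correlation of each planted edge with the residualized score."""
    keep = latent.cohort.mvic.notna().to_numpy()
    y = latent.cohort.mvic.to_numpy()[keep]
    X = np.column_stack([np.ones(keep.sum()),
                         latent.cohort.age.to_numpy()[keep],
                         latent.cohort.sex.to_numpy()[keep]])
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    edges = latent.fingerprint_matrix(0)[keep][:, latent.planted_edges]
    xc = edges - edges.mean(axis=0)
    yc = resid - resid.mean()
    return (xc * yc[:, None]).sum(0) / np.sqrt((xc**2).sum(0) * (yc**2).sum())


def conditioned_planted_cohort(base_seed, n_rois=60, window=(0.55, 0.68),
                               max_tries=60):
    """First cohort (scanning seeds from ``base_seed``) whose two planted
    edges realize |r| with the residualized score inside ``window``.

    The planted-effect calibration targets |r| = 0.6 in expectation; the
    realized per-cohort correlation fluctuates (sd ~ 0.09 at n = 52), so
    recovery properties are stated conditionally on the realized strength.
    """
    for k in range(max_tries):
        cfg = SynthConfig(n_rois=n_rois, planted_edge_count=2,
                          planted_weight_mean=6000.0, planted_weight_sd=0.0,
                          sigma_score=1881.0, seed=base_seed + k)
        lat = simulate_cohort(cfg)
        r = realized_planted_correlations(lat)
        if np.all((np.abs(r) >= window[0]) & (np.abs(r) <= window[1])):
            return lat
    raise RuntimeError("no cohort met the realized-correlation window")


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort shared across read-only tests."""
    cfg = SynthConfig(n_subjects=12, n_rois=30, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
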