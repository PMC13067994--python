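import numpy as np
import pytest

from cierstates.data_io import EMADataset
from cierstates.measurement_models import AttentiveGRM, CIERGRM
from cierstates.mixture_estimation import EstimationSettings


@pytest.fixture
def small_attentive():
    """3-item, 5-category attentive GRM with one negative item."""
    return AttentiveGRM(
        loadings=np.array([1.5, -1.0, 2.0]),
        thresholds=np.array([
            [2.0, 0.7, -0.6, -1.8],
            [1.5, 0.5, -0.5, -1.5],
            [2.2, 1.0, -0.2, -2.0],
        ]),
    )


@pytest.fixture
def small_cier():
    return CIERGRM(thresholds=np.array([1.2, 0.4, -0.4, -1.2]), pref_var=0.8)


@pytest.fixture
def fast_settings():
    """EM settings sized for quick unit tests, not precision."""
    return EstimationSettings(n_starts=2, n_finalists=1, burnin_iters=10,
                              max_iter=150, seed=7)


def make_dataset(Y, times=None, n_categories=7, covariates=None,
                 covariate_names=(), ids=None):
    Y = np.asarray(Y, dtype=float)
    n = len(Y)
    if ids is None:
        ids = np.zeros(n, dtype=int)
    occ = np.concatenate([np.arange(1, (ids == r).sum() + 1)
                          for r in np.unique(ids)])
    if times is None:
        times = occ.astype(float)
    return EMADataset(
        respondent_id=np.asarray(ids),
        occasion_index=occ,
        time_hours=np.asarray(times, dtype=float),
        responses=Y,
        n_categories=n_categories,
        covariates=covariates,
        covariate_names=list(covariate_names),
    )
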