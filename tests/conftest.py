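import itertools

import numpy as np
import pandas as pd
import pytest

from gllrasch.cml import ConditionalModel
from gllrasch.data import ResponseData, ScaleSpec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_model():
    """3 items x 3 categories PCM with fixed random parameters."""
    r = np.random.default_rng(7)
    cm = ConditionalModel(["a", "b", "c"], 2)
    theta = cm.layout.normalize_gauge(r.normal(0, 0.7, cm.layout.n_params))
    return cm, theta


@pytest.fixture(scope="session")
def small_gllrm():
    """3 items x 3 categories with one LD pair and one binary-covariate DIF."""
    r = np.random.default_rng(8)
    cm = ConditionalModel(["a", "b", "c"], 2, ld_pairs=[("a", "b")],
                          dif_terms=[("c", "g")],
                          cov_levels={"g": ["x", "y"]})
    theta = cm.layout.normalize_gauge(r.normal(0, 0.5, cm.layout.n_params))
    return cm, theta


def enumerate_logweights(cm, theta, profile_idx=0):
    """Brute-force oracle: all full patterns with their unnormalised
    log-weights, computed by independent summation over the parameter cells
    (never through the ESF tables)."""
    lay = cm.layout
    prof = dict(zip(cm.dif_covs, cm.profiles[profile_idx]))
    cats = [range(cm.max_cats[it] + 1) for it in cm.items]
    patterns, logws = [], []
    for pat in itertools.product(*cats):
        lw = 0.0
        for it, y in zip(cm.items, pat):
            if y > 0:
                lw += theta[lay.index[("alpha", it, y)]]
        for (i, j) in cm.ld_pairs:
            yi = pat[cm.items.index(i)]
            yj = pat[cm.items.index(j)]
            if yi > 0 and yj > 0:
                lw += theta[lay.index[("lambda", i, j, yi, yj)]]
        for (it, g) in cm.dif_terms:
            y = pat[cm.items.index(it)]
            lev = prof[g]
            if y > 0 and lev != cm.cov_levels[g][0]:
                lw += theta[lay.index[("delta", it, g, y, lev)]]
        patterns.append(pat)
        logws.append(lw)
    return np.array(patterns), np.array(logws)


def make_data(resp, items=None, covariates=None, covariate_levels=None, m=4):
    items = items if items is not None else [f"i{j}" for j in range(resp.shape[1])]
    spec = ScaleSpec("t", tuple(items), n_categories=m + 1)
    return ResponseData(np.arange(resp.shape[0]),
                        pd.DataFrame(resp, columns=items), spec,
                        covariates=covariates,
                        covariate_levels=dict(covariate_levels or {}))
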