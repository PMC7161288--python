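"""Fit, LD/DIF and dimensionality diagnostics for conditional Rasch models.

Covers the whole item-analysis battery: Andersen-type conditional
likelihood-ratio (CLR) tests of parameter invariance across score groups
(homogeneity) or covariate groups (global DIF); conditional infit/outfit
item-fit statistics with a conditional parametric bootstrap null; Kelderman
likelihood-ratio screening of candidate uniform LD / uniform DIF terms;
Goodman-Kruskal gamma and its stratified (partial) forms as effect sizes;
Benjamini-Hochberg adjustment; item-characteristic-curve tables; and the
two-subscale test of unidimensionality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import MISSING
from .model import GLLRM, GLLRMResults, ConvergenceError

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    """A chi-square scale test: statistic, degrees of freedom, p-value."""

    statistic: float
    df: int
    p_value: float
    grouping: str = ""
    note: str = ""

    def __str__(self):
        return (f"chi2({self.df}) = {self.statistic:.1f}, "
                f"p = {self.p_value:.4g}  [{self.grouping}]")


@dataclass
class GammaEstimate:
    """Goodman-Kruskal gamma (possibly partial) with asymptotic SE."""

    gamma: float
    se: float
    stratifier: str = "none"
    n: int = 0
    directional: dict = field(default_factory=dict)
    defined: bool = True


# ---------------------------------------------------------------------------
# conditional likelihood ratio tests
# ---------------------------------------------------------------------------

def _map_start(res: GLLRMResults, new_model: GLLRM):
    """Name-based warm start; None when category collapse changes the scale."""
    if new_model.category_maps or res.model.category_maps:
        return None
    start = np.zeros(new_model.cmodel.layout.n_params)
    for k, nm in enumerate(new_model.cmodel.layout.names):
        idx = res.cmodel.layout.index.get(nm)
        if idx is not None:
            start[k] = res.theta_full[idx]
    return start


def _fit_subgroup(res: GLLRMResults, mask, drop_cov=None, label=""):
    """Refit the model structure on a person subset, keeping pooled terms.

    DIF terms on ``drop_cov`` are removed: inside a single level of that
    covariate they are absorbed into the item parameters.
    """
    base = res.model
    dif = [t for t in base.dif if drop_cov is None or t[1] != drop_cov]
    sub = base.data.subset_persons(np.asarray(mask))
    try:
        m = GLLRM(sub, items=base.item_names, ld=base.ld, dif=dif)
    except ValueError as exc:
        raise ValueError(f"CLR subgroup {label!r}: {exc}") from exc
    return m.fit(start=_map_start(res, m), se=False)


def clr_test(res: GLLRMResults, grouping: str = "score",
             score_split: str = "median", method: str = "asymptotic",
             n_boot: int = 199, seed: int = 0) -> TestResult:
    """Conditional likelihood ratio test of item-parameter invariance.

    ``grouping="score"`` splits the sample at the median valid total score
    (ties to the low group) and tests overall fit (homogeneity); a covariate
    name splits by its levels and tests global DIF.  For GLLRMs the
    subgroup fits retain the pooled LD/DIF structure; DIF terms on the
    split covariate are dropped inside its levels, and the degrees of
    freedom are the sum of subgroup free-parameter counts minus the pooled
    count.

    The default p-value is asymptotic chi-square, which requires every
    category to be reasonably populated within every group; with sparse
    cells (rare extreme categories inside a score group) the statistic is
    inflated relative to chi-square.  ``method="bootstrap"`` instead draws
    response patterns conditionally on every person's observed (score,
    profile) from the fitted model and recomputes the statistic, an exact
    conditional null that is insensitive to sparseness.
    """
    base = res.model
    grouped = base.grouped
    usable = grouped.complete.copy()
    if grouping == "score":
        scores = grouped.scores[usable]
        med = np.median(scores)
        labels = np.where(grouped.scores <= med, "low", "high")
        drop_cov = None
        levels = ["low", "high"]
    else:
        cov = base.data.covariates[grouping]
        usable &= cov.notna().to_numpy()
        labels = cov.to_numpy()
        levels = base.data.covariate_levels.get(
            grouping, sorted(pd.unique(cov.dropna())))
        drop_cov = grouping
    masks = []
    for lev in levels:
        mask = usable & (labels == lev)
        if not mask.any():
            raise ValueError(f"CLR group {lev!r} is empty")
        masks.append(mask)

    def _stat(fitted):
        ll_groups, df_groups = 0.0, 0
        for lev, mask in zip(levels, masks):
            r = _fit_subgroup(fitted, mask, drop_cov=drop_cov, label=str(lev))
            ll_groups += r.llf
            df_groups += r.df_model
        return (max(2.0 * (ll_groups - fitted.llf), 0.0),
                df_groups - fitted.df_model)

    stat, df = _stat(res)
    label = f"{grouping} ({len(levels)} groups)"
    if method == "asymptotic":
        return TestResult(stat, df, float(stats.chi2.sf(stat, df)),
                          grouping=label)

    rng = np.random.default_rng(seed)
    tabs = res.tables()
    work = base.responses_work
    count = 0
    for _ in range(n_boot):
        sim = work.copy()
        for ci in np.unique(grouped.profile_idx[usable]):
            m = usable & (grouped.profile_idx == ci)
            sim[m] = tabs.sample_conditional(rng, grouped.scores[m], int(ci))
        new = base.data.with_responses(
            pd.DataFrame(_expand_categories(base, sim),
                         columns=list(base.item_names)))
        mdl = GLLRM(new, items=base.item_names, ld=base.ld, dif=base.dif)
        fitb = mdl.fit(start=_map_start(res, mdl), se=False)
        stat_b, _ = _stat(fitb)
        count += stat_b >= stat
    p = (1.0 + count) / (1.0 + n_boot)
    return TestResult(stat, df, p, grouping=label,
                      note=f"conditional bootstrap, B={n_boot}")


def _expand_categories(model: GLLRM, work: np.ndarray) -> np.ndarray:
    """Map working (collapsed) category codes back to the original coding."""
    if not model.category_maps:
        return work
    out = work.copy()
    for col, it in enumerate(model.item_names):
        amap = model.category_maps.get(it)
        if not amap:
            continue
        inv = {v: k for k, v in amap.items()}
        ok = out[:, col] >= 0
        out[ok, col] = np.vectorize(inv.get)(out[ok, col])
    return out


# ---------------------------------------------------------------------------
# conditional item fit
# ---------------------------------------------------------------------------

def _fit_statistics(resp, scores, prof, E, V, items):
    """Vectorised conditional outfit/infit for one response matrix."""
    out = np.empty((len(items), 2))
    for k, it in enumerate(items):
        e = np.empty(len(scores))
        v = np.empty(len(scores))
        for ci in np.unique(prof):
            m = prof == ci
            e[m] = E[ci][it][scores[m]]
            v[m] = V[ci][it][scores[m]]
        ok = v > 1e-12
        d2 = (resp[:, k] - e) ** 2
        out[k, 0] = np.mean(d2[ok] / v[ok])          # outfit
        out[k, 1] = d2[ok].sum() / v[ok].sum()       # infit
    return out


def conditional_item_fit(res: GLLRMResults, n_boot: int = 400,
                         seed: int = 0, refit: bool = True) -> pd.DataFrame:
    """Conditional infit and outfit statistics with bootstrap SE and p.

    Residuals use conditional item moments given (total score, covariate
    profile) at the estimates; both statistics have expectation 1 under the
    model.  The null distribution is a parametric bootstrap drawn
    conditionally on every person's observed (score, profile), which fixes
    the sufficient statistics of the person side and the DIF structure.
    With ``refit`` (default) every replicate is re-estimated by a one-step
    Newton update from the observed-data estimate -- asymptotically
    equivalent to a full CML refit -- so that the null distribution
    reflects the same estimation shrinkage as the observed statistic;
    without it the p-values are conservative.

    Both statistics are means of ~n bounded terms and hence asymptotically
    normal; the two-sided p-value is the studentized normal probability at
    the bootstrap-estimated conditional mean and SE, which calibrates the
    far tail better than raw bootstrap ranks at moderate replicate counts.
    """
    rng = np.random.default_rng(seed)
    model = res.model
    g = model.grouped
    use = g.nonextreme
    resp = model.responses_work[use]
    scores = g.scores[use]
    prof = g.profile_idx[use]
    items = list(res.cmodel.items)
    tabs = res.tables()
    nprof = len(res.cmodel.profiles)
    E = [None] * nprof
    V = [None] * nprof
    for ci in np.unique(prof):
        E[ci], V[ci] = tabs.item_moments(int(ci))

    obs = _fit_statistics(resp, scores, prof, E, V, items)

    if refit:
        from scipy.linalg import cho_factor, cho_solve

        lay = res.cmodel.layout
        estimable = getattr(res, "estimable", None)
        J = lay.jacobian(estimable)
        u_hat = lay.free_from_full(res.theta_full, estimable)
        H_u = J.T @ tabs.information_matrix(g.n_by_score) @ J
        factor = cho_factor(H_u + 1e-10 * np.eye(H_u.shape[0]))
        expected_t = g.t - g.score_vector(tabs)

    boot = np.empty((n_boot, len(items), 2))
    sim = np.empty_like(resp)
    for b in range(n_boot):
        for ci in np.unique(prof):
            m = prof == ci
            sim[m] = tabs.sample_conditional(rng, scores[m], int(ci))
        if refit:
            t_b = g.feature_totals(sim, prof)
            u_b = u_hat + cho_solve(factor, J.T @ (t_b - expected_t))
            tabs_b = res.cmodel.tables(
                lay.full_from_free(u_b, estimable))
            E_b = [None] * nprof
            V_b = [None] * nprof
            for ci in np.unique(prof):
                E_b[ci], V_b[ci] = tabs_b.item_moments(int(ci))
            boot[b] = _fit_statistics(sim, scores, prof, E_b, V_b, items)
        else:
            boot[b] = _fit_statistics(sim, scores, prof, E, V, items)

    rows = []
    for k, it in enumerate(items):
        rec = {"item": it, "n": int(use.sum())}
        for j, name in enumerate(("outfit", "infit")):
            t = obs[k, j]
            bt = boot[:, k, j]
            se = float(bt.std(ddof=1))
            z = (t - float(bt.mean())) / se if se > 0 else np.nan
            rec[name] = t
            rec[f"{name}_se"] = se
            rec[f"{name}_p"] = float(2 * stats.norm.sf(abs(z)))
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kelderman likelihood-ratio screening
# ---------------------------------------------------------------------------

def kelderman_lr(res: GLLRMResults, candidate) -> TestResult:
    """LR test of one additional uniform LD or uniform DIF term.

    ``candidate`` is ``("ld", item_i, item_j)`` or ``("dif", item, cov)``.
    The statistic is 2(l_augmented - l_base) with df equal to the number of
    additional estimable interaction cells.
    """
    kind = candidate[0]
    base = res.model
    if kind == "ld":
        pair = (candidate[1], candidate[2])
        if not set(pair) <= set(base.item_names):
            raise ValueError(f"LD pair {pair!r} not in the analysis item set")
        if frozenset(pair) in {frozenset(p) for p in base.ld}:
            raise ValueError(f"LD pair {pair!r} already in the model")
        ld, dif = list(base.ld) + [pair], list(base.dif)
        label = f"LD {pair[0]}~{pair[1]}"
    elif kind == "dif":
        term = (candidate[1], candidate[2])
        if term[0] not in base.item_names:
            raise ValueError(f"DIF item {term[0]!r} not in the analysis set")
        if term[1] not in base.data.covariates.columns:
            raise ValueError(f"DIF covariate {term[1]!r} not in the data")
        if term in set(base.dif):
            raise ValueError(f"DIF term {term!r} already in the model")
        ld, dif = list(base.ld), list(base.dif) + [term]
        label = f"DIF {term[0]}×{term[1]}"
    else:
        raise ValueError(f"unknown candidate kind {kind!r}")
    try:
        aug = GLLRM(base.data, items=base.item_names, ld=ld, dif=dif)
        fit = aug.fit(start=_map_start(res, aug), se=False)
    except (ConvergenceError, ValueError) as exc:
        logger.warning("Kelderman augmented fit failed (%s): %s", label, exc)
        return TestResult(np.nan, 0, np.nan, grouping=label,
                          note="inconclusive: augmented fit failed")
    stat = max(2.0 * (fit.llf - res.llf), 0.0)
    df = fit.df_model - res.df_model
    if df <= 0:
        return TestResult(stat, 0, np.nan, grouping=label,
                          note="inconclusive: no estimable added cells")
    return TestResult(stat, df, float(stats.chi2.sf(stat, df)), grouping=label)


# ---------------------------------------------------------------------------
# Goodman-Kruskal gamma
# ---------------------------------------------------------------------------

def _gamma_from_table(tab: np.ndarray):
    """(gamma, var, P, Q) from a 2-way count table; pairs counted twice."""
    n = np.asarray(tab, dtype=float)
    R, C = n.shape
    P = np.zeros((R + 1, C + 1))
    P[1:, 1:] = n.cumsum(0).cumsum(1)
    total = P[R, C]
    i = np.arange(R)[:, None]
    j = np.arange(C)[None, :]
    lt_lt = P[i, j]
    gt_gt = total - P[i + 1, C] - P[R, j + 1] + P[i + 1, j + 1]
    lt_gt = P[i, C] - P[i, j + 1]
    gt_lt = P[R, j] - P[i + 1, j]
    A = lt_lt + gt_gt
    D = lt_gt + gt_lt
    Pc = float((n * A).sum())
    Qc = float((n * D).sum())
    if Pc + Qc == 0:
        return np.nan, np.nan, Pc, Qc
    gamma = (Pc - Qc) / (Pc + Qc)
    var = 16.0 * float((n * (Qc * A - Pc * D) ** 2).sum()) / (Pc + Qc) ** 4
    return gamma, var, Pc, Qc


def gamma_coefficient(x, y) -> GammaEstimate:
    """Goodman-Kruskal gamma rank correlation with asymptotic SE."""
    x = np.asarray(x)
    y = np.asarray(y)
    ok = ~(pd.isna(x) | pd.isna(y))
    x, y = x[ok], y[ok]
    xi = pd.factorize(x, sort=True)[0]
    yi = pd.factorize(y, sort=True)[0]
    tab = np.zeros((xi.max() + 1, yi.max() + 1)) if len(xi) else np.zeros((1, 1))
    np.add.at(tab, (xi, yi), 1)
    g, var, Pc, Qc = _gamma_from_table(tab)
    if not np.isfinite(g):
        return GammaEstimate(np.nan, np.nan, n=len(x), defined=False)
    return GammaEstimate(float(g), float(np.sqrt(max(var, 0.0))), n=len(x))


def _pooled_partial_gamma(x, y, strata):
    """Inverse-variance pooled gamma within strata of a stratifier."""
    gs, ws = [], []
    for s in np.unique(strata):
        m = strata == s
        if m.sum() < 2:
            continue
        xi = pd.factorize(x[m], sort=True)[0]
        yi = pd.factorize(y[m], sort=True)[0]
        tab = np.zeros((xi.max() + 1, yi.max() + 1))
        np.add.at(tab, (xi, yi), 1)
        g, var, Pc, Qc = _gamma_from_table(tab)
        if not np.isfinite(g) or var <= 0:
            # strata with no discordant/concordant mix (gamma = +-1 exactly)
            # carry zero asymptotic information and are dropped
            continue
        gs.append(g)
        ws.append(1.0 / var)
    if not gs:
        return np.nan, np.nan
    gs, ws = np.asarray(gs), np.asarray(ws)
    return float((ws * gs).sum() / ws.sum()), float(np.sqrt(1.0 / ws.sum()))


def partial_gamma_ld(data, item_i: str, item_j: str, item_set) -> GammaEstimate:
    """Partial gamma between two items given the two restscores.

    Gamma is pooled over strata of R - y_i and, separately, of R - y_j;
    the headline value is the mean of the two directional partial gammas
    (both are reported).
    """
    if item_i == item_j:
        raise ValueError("item paired with itself")
    item_set = list(item_set)
    if item_i not in item_set or item_j not in item_set:
        raise ValueError("both items must belong to the item set")
    mat = data.matrix(item_set)
    ok = (mat != MISSING).all(axis=1)
    mat = mat[ok]
    yi = mat[:, item_set.index(item_i)]
    yj = mat[:, item_set.index(item_j)]
    total = mat.sum(axis=1)
    g1, se1 = _pooled_partial_gamma(yi, yj, total - yi)
    g2, se2 = _pooled_partial_gamma(yi, yj, total - yj)
    vals = [v for v in (g1, g2) if np.isfinite(v)]
    if not vals:
        return GammaEstimate(np.nan, np.nan, stratifier="restscores",
                             defined=False)
    g_avg = float(np.mean(vals))
    ses = [s for s in (se1, se2) if np.isfinite(s)]
    se = float(0.5 * np.sqrt(np.sum(np.square(ses)))) if len(ses) == 2 \
        else float(ses[0])
    return GammaEstimate(g_avg, se, stratifier="restscores", n=int(ok.sum()),
                         directional={"given_rest_i": g1, "given_rest_j": g2})


def partial_gamma_dif(data, item: str, covariate: str, item_set) -> GammaEstimate:
    """Partial gamma between an item and a covariate given the total score."""
    item_set = list(item_set)
    if item not in item_set:
        raise ValueError("item must belong to the item set")
    mat = data.matrix(item_set)
    cov = data.covariates[covariate]
    levels = data.covariate_levels.get(covariate,
                                       sorted(pd.unique(cov.dropna())))
    if len(pd.unique(cov.dropna())) < 2:
        raise ValueError(f"covariate {covariate!r} has a single observed level")
    code = cov.map({lev: k for k, lev in enumerate(levels)}).to_numpy(dtype=float)
    ok = (mat != MISSING).all(axis=1) & np.isfinite(code)
    y = mat[ok, item_set.index(item)]
    total = mat[ok].sum(axis=1)
    g, se = _pooled_partial_gamma(y, code[ok], total)
    if not np.isfinite(g):
        return GammaEstimate(np.nan, np.nan, stratifier="total score",
                             defined=False)
    return GammaEstimate(g, se, stratifier="total score", n=int(ok.sum()))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    ok = np.isfinite(p)
    out = np.full_like(p, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# item characteristic curve tables
# ---------------------------------------------------------------------------

def icc_table(res: GLLRMResults, item: str) -> pd.DataFrame:
    """Observed vs model-expected mean item score per total score.

    Expected means mix the covariate profiles with their observed
    frequencies at each score; the 95% band is for the observed mean of
    n_r persons.  Scores observed by nobody are omitted.
    """
    model = res.model
    g = model.grouped
    use = g.complete
    k = list(res.cmodel.items).index(item)
    resp = model.responses_work[use]
    scores = g.scores[use]
    prof = g.profile_idx[use]
    tabs = res.tables()
    E, V = {}, {}
    for ci in np.unique(prof):
        E[ci], V[ci] = tabs.item_moments(int(ci))
    rows = []
    for r in np.unique(scores):
        m = scores == r
        n_r = int(m.sum())
        evals = np.array([E[ci][item][r] for ci in prof[m]])
        vvals = np.array([V[ci][item][r] for ci in prof[m]])
        exp_mean = evals.mean()
        band = 1.96 * np.sqrt(vvals.sum()) / n_r
        rows.append({"score": int(r), "n": n_r,
                     "observed": float(resp[m, k].mean()),
                     "expected": float(exp_mean),
                     "lower": float(exp_mean - band),
                     "upper": float(exp_mean + band)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# unidimensionality
# ---------------------------------------------------------------------------

@dataclass
class UnidimResult:
    gamma_obs: float
    gamma_exp: float
    se: float
    p_value: float
    n: int


def unidimensionality_test(res_a: GLLRMResults, res_b: GLLRMResults,
                           n_sim: int = 200_000, n_boot: int = 200,
                           seed: int = 0) -> UnidimResult:
    """Observed vs expected-under-unidimensionality subscale correlation.

    Both subscales must be scored in the same direction (reverse scoring
    already applied).  The expected gamma is obtained by Monte Carlo from
    the two fitted models driven by a *common* latent variable: z ~ N(0,1)
    is mapped to each subscale's estimated person distribution, responses
    are drawn from the fitted conditional structures, and gamma is computed
    on the simulated subscale scores.  One-sided test: an observed gamma
    below the expected one argues against unidimensionality.
    """
    from .scoring import estimate_person_dist

    a_items = set(res_a.cmodel.items)
    b_items = set(res_b.cmodel.items)
    if a_items & b_items:
        raise ValueError("subscales share items; item sets must be disjoint")
    if res_a.model.data is not res_b.model.data and \
            len(res_a.model.data.person_id) != len(res_b.model.data.person_id):
        raise ValueError("subscale models must be fitted on the same persons")

    ga = res_a.model.grouped
    gb = res_b.model.grouped
    both = ga.complete & gb.complete
    n = int(both.sum())
    sa = ga.scores[both]
    sb = gb.scores[both]
    obs = gamma_coefficient(sa, sb)
    if not obs.defined:
        raise ValueError("observed subscale gamma is undefined")

    rng = np.random.default_rng(seed)
    da = estimate_person_dist(res_a)
    db = estimate_person_dist(res_b)
    prof_a = ga.profile_idx[both]
    prof_b = gb.profile_idx[both]
    pick = rng.integers(0, n, size=n_sim)
    z = rng.standard_normal(n_sim)
    ta = da.mean + da.sd * z
    tb = db.mean + db.sd * z
    ya = res_a.tables().sample_given_theta(rng, ta, prof_a[pick])
    yb = res_b.tables().sample_given_theta(rng, tb, prof_b[pick])
    ra = ya.sum(axis=1)
    rb = yb.sum(axis=1)
    g_exp = gamma_coefficient(ra, rb)

    # MC error of the expectation from independent blocks
    nblock = 20
    block = n_sim // nblock
    gs = [gamma_coefficient(ra[i * block:(i + 1) * block],
                            rb[i * block:(i + 1) * block]).gamma
          for i in range(nblock)]
    se_exp = float(np.std(gs, ddof=1) / np.sqrt(nblock))

    # bootstrap SE of the observed gamma
    bo = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bo[b] = gamma_coefficient(sa[idx], sb[idx]).gamma
    se_obs = float(bo.std(ddof=1))

    se = float(np.sqrt(se_obs ** 2 + se_exp ** 2))
    zstat = (obs.gamma - g_exp.gamma) / se
    p = float(stats.norm.cdf(zstat))       # observed < expected => small p
    return UnidimResult(float(obs.gamma), float(g_exp.gamma), se, p, n)
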