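"""Conditional inference engine for polytomous Rasch models.

Everything here conditions on the total score R = sum_i Y_i, which is the
sufficient statistic for the person parameter in the (partial credit) Rasch
model and remains sufficient -- within covariate-defined subgroups -- when
uniform local-dependence (LD) and uniform differential-item-functioning
(DIF) interaction terms are added.

The combinatorial backbone is the elementary symmetric function (ESF)

    gamma_r = sum over response patterns y with sum(y) = r of
              exp( sum_i alpha^i_{y_i} + LD terms + DIF terms )

computed strictly in log space.  Locally dependent items are grouped into
*components* (connected components of the LD graph); each component behaves
as a composite item whose score-weight table is obtained by enumerating its
internal patterns, and the ESF over components is built by log-space
convolution.  DIF enters through covariate *profiles*: each distinct
combination of DIF-covariate levels has its own effective parameter tables.

Parameterisation
----------------
* ``alpha`` item-category parameters, one free cell per (item, y) with
  y = 1..m_i and alpha^i_0 = 0.  One linear gauge freedom
  (alpha^i_y -> alpha^i_y + c*y for every item) is removed by the sum-zero
  identification  sum_i alpha^i_{m_i} / m_i = 0  (equal item locations sum
  to zero).
* ``lambda`` uniform LD cells, one per (pair, y_i, y_j) with y_i, y_j >= 1
  (corner constraint: any zero index fixes the cell at 0).
* ``delta`` uniform DIF cells, one per (item, covariate, y, level) with
  y >= 1 and level != reference level.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

NEG_INF = -np.inf


# ---------------------------------------------------------------------------
# log-space table algebra
# ---------------------------------------------------------------------------

def logsumexp_rows(vals: np.ndarray) -> np.ndarray:
    """Row-wise logsumexp tolerating all -inf rows (which map to -inf)."""
    mx = vals.max(axis=-1)
    safe = np.where(np.isfinite(mx), mx, 0.0)
    with np.errstate(invalid="ignore"):
        out = safe + np.log(np.exp(vals - safe[..., None]).sum(axis=-1))
    return np.where(np.isfinite(mx), out, NEG_INF)


def log_convolve(la: np.ndarray, lb: np.ndarray) -> np.ndarray:
    """Log-space convolution of two score-weight tables.

    ``la[r]`` and ``lb[s]`` are log-weights of scores r and s; the result
    has length ``len(la) + len(lb) - 1`` with entries
    log sum_{r+s=t} exp(la[r] + lb[s]).
    """
    A, B = la.size - 1, lb.size - 1
    t = np.arange(A + B + 1)[:, None]
    s = np.arange(B + 1)[None, :]
    i = t - s
    valid = (i >= 0) & (i <= A)
    vals = np.where(valid, la[np.clip(i, 0, A)] + lb[s], NEG_INF)
    return logsumexp_rows(vals)


# ---------------------------------------------------------------------------
# structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Component:
    """A maximal set of mutually locally-dependent items (singleton if none)."""

    items: tuple
    item_idx: tuple
    patterns: np.ndarray      # (P, len(items)) internal category patterns
    scores: np.ndarray        # (P,) pattern scores
    max_score: int


def _normalize_ld_pairs(ld_pairs, items):
    seen = set()
    out = []
    for pair in ld_pairs:
        i, j = tuple(pair)
        if i == j:
            raise ValueError(f"LD pair with identical items: {i!r}")
        if i not in items or j not in items:
            raise ValueError(f"LD pair {pair!r} references items outside the set")
        key = frozenset((i, j))
        if key in seen:
            raise ValueError(f"duplicate LD pair {pair!r}")
        seen.add(key)
        # keep item order as in the item list for a canonical orientation
        a, b = sorted((i, j), key=items.index)
        out.append((a, b))
    return tuple(out)


class ParamLayout:
    """Index bookkeeping for the free parameters of a (GLL)RM.

    Full parameter vector order: alpha cells, lambda cells, delta cells.
    ``names`` holds a describing tuple per cell.  The free vector maps to
    the full vector through the orthonormal basis ``B`` of the identified
    alpha subspace plus the identity on interaction cells.
    """

    def __init__(self, items, max_cats, ld_pairs, dif_terms, cov_levels):
        self.items = tuple(items)
        self.max_cats = dict(max_cats)
        self.names = []
        self.alpha_slice = None
        for it in self.items:
            for y in range(1, self.max_cats[it] + 1):
                self.names.append(("alpha", it, y))
        n_alpha = len(self.names)
        self.alpha_slice = slice(0, n_alpha)
        for (i, j) in ld_pairs:
            for yi in range(1, self.max_cats[i] + 1):
                for yj in range(1, self.max_cats[j] + 1):
                    self.names.append(("lambda", i, j, yi, yj))
        for (it, cov) in dif_terms:
            levels = cov_levels[cov]
            for y in range(1, self.max_cats[it] + 1):
                for lev in levels[1:]:
                    self.names.append(("delta", it, cov, y, lev))
        self.n_params = len(self.names)
        self.n_alpha = n_alpha
        self.index = {nm: k for k, nm in enumerate(self.names)}

        # identification: sum over items of alpha^i_{m_i} / m_i = 0
        a = np.zeros(n_alpha)
        for it in self.items:
            a[self.index[("alpha", it, self.max_cats[it])]] = 1.0 / self.max_cats[it]
        self._constraint = a
        self.B = null_space(a[None, :])          # (n_alpha, n_alpha - 1)
        # gauge direction alpha^i_y -> alpha^i_y + c * y
        g = np.zeros(n_alpha)
        for k, nm in enumerate(self.names[:n_alpha]):
            g[k] = nm[2]
        self._gauge = g
        self.n_free = self.n_params - 1

    # -- free <-> full -----------------------------------------------------
    def full_from_free(self, u: np.ndarray, estimable=None) -> np.ndarray:
        theta = np.zeros(self.n_params)
        na = self.n_alpha
        theta[:na] = self.B @ u[: na - 1]
        if estimable is None:
            theta[na:] = u[na - 1:]
        else:
            inter = np.zeros(self.n_params - na)
            inter[estimable[na:]] = u[na - 1:]
            theta[na:] = inter
        return theta

    def free_from_full(self, theta: np.ndarray, estimable=None) -> np.ndarray:
        theta = self.normalize_gauge(theta)
        na = self.n_alpha
        u_alpha = self.B.T @ theta[:na]
        inter = theta[na:]
        if estimable is not None:
            inter = inter[estimable[na:]]
        return np.concatenate([u_alpha, inter])

    def normalize_gauge(self, theta: np.ndarray) -> np.ndarray:
        """Shift along the gauge orbit so the sum-zero identification holds."""
        theta = np.array(theta, dtype=float)
        a, g = self._constraint, self._gauge
        t = (a @ theta[: self.n_alpha]) / (a @ g)
        theta[: self.n_alpha] -= t * g
        return theta

    def jacobian(self, estimable=None) -> np.ndarray:
        """d(theta_full)/d(u_free), used to map covariances back."""
        na = self.n_alpha
        n_inter = self.n_params - na
        if estimable is None:
            keep = np.arange(n_inter)
        else:
            keep = np.flatnonzero(estimable[na:])
        J = np.zeros((self.n_params, na - 1 + keep.size))
        J[:na, : na - 1] = self.B
        for col, row in enumerate(keep):
            J[na + row, na - 1 + col] = 1.0
        return J

    def alpha_array(self, theta: np.ndarray, item: str) -> np.ndarray:
        """alpha^i_y for y = 0..m_i (alpha^i_0 = 0)."""
        m = self.max_cats[item]
        out = np.zeros(m + 1)
        for y in range(1, m + 1):
            out[y] = theta[self.index[("alpha", item, y)]]
        return out


class ConditionalModel:
    """Structure of a partial-credit / graphical log-linear Rasch model.

    Parameters
    ----------
    items : sequence of str
        Analysis item set, in order.
    max_cats : dict or int
        Highest category code m_i per item.
    ld_pairs : sequence of (item, item)
        Unordered pairs declared locally dependent.
    dif_terms : sequence of (item, covariate)
        Items with uniform DIF by the named covariate.
    cov_levels : dict
        Level list per DIF covariate, reference level first.
    """

    def __init__(self, items, max_cats, ld_pairs=(), dif_terms=(), cov_levels=None):
        self.items = tuple(items)
        if isinstance(max_cats, int):
            max_cats = {it: max_cats for it in self.items}
        self.max_cats = {it: int(max_cats[it]) for it in self.items}
        self.ld_pairs = _normalize_ld_pairs(ld_pairs, self.items)
        self.dif_terms = tuple((it, cov) for it, cov in dif_terms)
        for it, cov in self.dif_terms:
            if it not in self.items:
                raise ValueError(f"DIF item {it!r} not in item set")
        if self.dif_terms and not cov_levels:
            raise ValueError("cov_levels required when DIF terms are present")
        self.dif_covs = []
        for _, cov in self.dif_terms:
            if cov not in self.dif_covs:
                self.dif_covs.append(cov)
        self.cov_levels = {g: list(cov_levels[g]) for g in self.dif_covs} \
            if cov_levels else {}
        for g in self.dif_covs:
            if len(self.cov_levels[g]) < 2:
                raise ValueError(f"DIF covariate {g!r} needs >= 2 levels")

        self.layout = ParamLayout(self.items, self.max_cats, self.ld_pairs,
                                  self.dif_terms, self.cov_levels)
        self.max_score = sum(self.max_cats.values())
        self._build_components()
        self.profiles = list(itertools.product(
            *[self.cov_levels[g] for g in self.dif_covs])) or [()]
        self._build_design()

    # -- structure ---------------------------------------------------------
    def _build_components(self):
        parent = {it: it for it in self.items}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in self.ld_pairs:
            parent[find(i)] = find(j)
        groups = {}
        for it in self.items:
            groups.setdefault(find(it), []).append(it)
        comps = []
        seen = set()
        for it in self.items:              # deterministic order
            root = find(it)
            if root in seen:
                continue
            seen.add(root)
            members = tuple(sorted(groups[root], key=self.items.index))
            cats = [range(self.max_cats[m] + 1) for m in members]
            patterns = np.array(list(itertools.product(*cats)), dtype=np.int64)
            comps.append(Component(
                items=members,
                item_idx=tuple(self.items.index(m) for m in members),
                patterns=patterns,
                scores=patterns.sum(axis=1),
                max_score=int(sum(self.max_cats[m] for m in members)),
            ))
        self.components = comps

    def _build_design(self):
        """Binary feature matrices M[(profile, comp)] : patterns x params."""
        lay = self.layout
        self._M = {}
        for ci, prof in enumerate(self.profiles):
            prof_level = dict(zip(self.dif_covs, prof))
            for ki, comp in enumerate(self.components):
                P = comp.patterns.shape[0]
                M = np.zeros((P, lay.n_params))
                for col, it in enumerate(comp.items):
                    ys = comp.patterns[:, col]
                    for y in range(1, self.max_cats[it] + 1):
                        M[ys == y, lay.index[("alpha", it, y)]] = 1.0
                for (i, j) in self.ld_pairs:
                    if i not in comp.items:
                        continue
                    yi = comp.patterns[:, comp.items.index(i)]
                    yj = comp.patterns[:, comp.items.index(j)]
                    for p in range(P):
                        if yi[p] >= 1 and yj[p] >= 1:
                            M[p, lay.index[("lambda", i, j, yi[p], yj[p])]] = 1.0
                for (it, cov) in self.dif_terms:
                    if it not in comp.items:
                        continue
                    lev = prof_level[cov]
                    if lev == self.cov_levels[cov][0]:
                        continue
                    ys = comp.patterns[:, comp.items.index(it)]
                    for y in range(1, self.max_cats[it] + 1):
                        M[ys == y, lay.index[("delta", it, cov, y, lev)]] = 1.0
                self._M[(ci, ki)] = M

    def design(self, profile_idx: int, comp_idx: int) -> np.ndarray:
        return self._M[(profile_idx, comp_idx)]

    def profile_index(self, covariates_row: dict) -> int:
        """Index of the covariate profile a person belongs to."""
        key = tuple(covariates_row[g] for g in self.dif_covs)
        return self.profiles.index(key)

    def profile_indices(self, covariates) -> np.ndarray:
        """Vectorised profile lookup from a covariate DataFrame."""
        if not self.dif_covs:
            return np.zeros(len(covariates), dtype=np.int64)
        keys = list(zip(*[covariates[g].to_numpy() for g in self.dif_covs]))
        lut = {p: k for k, p in enumerate(self.profiles)}
        return np.array([lut[k] for k in keys], dtype=np.int64)

    def n_free_params(self) -> int:
        return self.layout.n_free

    def tables(self, theta_full: np.ndarray) -> "ModelTables":
        return ModelTables(self, np.asarray(theta_full, dtype=float))

    # -- convenience constructors -----------------------------------------
    def pcm_submodel(self) -> "ConditionalModel":
        return ConditionalModel(self.items, self.max_cats)


def model_dof(model: ConditionalModel, estimable=None) -> int:
    """Free-parameter count: sum m_i - 1 base plus interaction cells.

    A 14-item five-category pure RM has 14*4 - 1 = 55; a 7-item one has 27.
    Cells frozen at zero because their margin was never observed are not
    counted when an ``estimable`` mask is supplied.
    """
    if estimable is None:
        return model.layout.n_free
    na = model.layout.n_alpha
    return (na - 1) + int(np.count_nonzero(estimable[na:]))


# ---------------------------------------------------------------------------
# parameter-dependent tables
# ---------------------------------------------------------------------------

class ModelTables:
    """All score-weight tables of a model at a fixed parameter vector.

    Provides ESF tables per covariate profile, component-deleted tables,
    conditional pattern probabilities, conditional item moments, and exact
    samplers (conditional on the total score, or given a latent trait value).
    """

    def __init__(self, model: ConditionalModel, theta_full: np.ndarray):
        self.model = model
        self.theta = theta_full
        C = len(model.components)
        self.logw = {}        # (profile, comp) -> (P,)
        self.zeta = {}        # (profile, comp) -> (S_comp+1,)
        self.prefix = {}      # (profile, j) -> table of comps < j
        self.suffix = {}      # (profile, j) -> table of comps >= j
        self.loggamma = {}    # profile -> (R_max+1,)
        for ci in range(len(model.profiles)):
            for ki, comp in enumerate(model.components):
                lw = model.design(ci, ki) @ theta_full
                self.logw[(ci, ki)] = lw
                S = comp.max_score
                vals = np.full((S + 1, lw.size), NEG_INF)
                vals[comp.scores, np.arange(lw.size)] = lw
                self.zeta[(ci, ki)] = logsumexp_rows(vals)
            pre = np.zeros(1)
            self.prefix[(ci, 0)] = pre
            for j in range(C):
                pre = log_convolve(pre, self.zeta[(ci, j)])
                self.prefix[(ci, j + 1)] = pre
            suf = np.zeros(1)
            self.suffix[(ci, C)] = suf
            for j in range(C - 1, -1, -1):
                suf = log_convolve(self.zeta[(ci, j)], suf)
                self.suffix[(ci, j)] = suf
            self.loggamma[ci] = self.prefix[(ci, C)]
        self._item_probs_cache = {}

    # -- ESF accessors -----------------------------------------------------
    def esf(self, profile_idx: int = 0) -> np.ndarray:
        """log gamma_r for r = 0..R_max (log gamma_0 = 0 by construction)."""
        return self.loggamma[profile_idx]

    def deleted(self, profile_idx: int, comp_idx: int) -> np.ndarray:
        """ESF table with one component removed."""
        return log_convolve(self.prefix[(profile_idx, comp_idx)],
                            self.suffix[(profile_idx, comp_idx + 1)])

    # -- conditional probabilities ------------------------------------------
    def loglik_groups(self, n_by_score: np.ndarray, profile_idx: int = 0) -> float:
        """- sum_r n_r log gamma_r (normalising part of the loglik)."""
        lg = self.loggamma[profile_idx]
        return -float(n_by_score @ lg)

    def pattern_logprob(self, pattern, r: int, profile_idx: int = 0) -> float:
        """log P(Y = pattern | R = r, profile) for a full response pattern."""
        pattern = np.asarray(pattern)
        if int(pattern.sum()) != int(r):
            raise ValueError("pattern total does not equal the stated score r")
        lp = 0.0
        for ki, comp in enumerate(self.model.components):
            sub = tuple(pattern[list(comp.item_idx)])
            pidx = np.flatnonzero((comp.patterns == sub).all(axis=1))[0]
            lp += self.logw[(profile_idx, ki)][pidx]
        return lp - self.loggamma[profile_idx][int(r)]

    def expected_pattern_counts(self, n_by_score: np.ndarray, profile_idx: int,
                                comp_idx: int) -> np.ndarray:
        """sum_r n_r P(component pattern | R = r) for one component."""
        comp = self.model.components[comp_idx]
        lw = self.logw[(profile_idx, comp_idx)]
        dele = self.deleted(profile_idx, comp_idx)
        lg = self.loggamma[profile_idx]
        R = lg.size - 1
        r = np.arange(R + 1)[:, None]
        sp = comp.scores[None, :]
        rem = r - sp
        ok = (rem >= 0) & (rem <= dele.size - 1)
        with np.errstate(invalid="ignore"):
            logP = np.where(ok, lw[None, :] + dele[np.clip(rem, 0, dele.size - 1)]
                            - lg[:, None], NEG_INF)
        return n_by_score @ np.exp(logP)

    def component_score_totals(self, n_by_score: np.ndarray, profile_idx: int,
                               comp_idx: int, comp_idx2: int) -> np.ndarray:
        """T[s] = sum_r n_r exp(del2[r-s] - loggamma[r]) for a component pair."""
        dele2 = self.deleted2(profile_idx, comp_idx, comp_idx2)
        lg = self.loggamma[profile_idx]
        R = lg.size - 1
        smax = self.model.components[comp_idx].max_score + \
            self.model.components[comp_idx2].max_score
        s = np.arange(smax + 1)[:, None]
        r = np.arange(R + 1)[None, :]
        rem = r - s
        ok = (rem >= 0) & (rem <= dele2.size - 1)
        with np.errstate(invalid="ignore"):
            vals = np.where(ok, dele2[np.clip(rem, 0, dele2.size - 1)]
                            - lg[None, :], NEG_INF)
        return np.exp(vals) @ n_by_score

    def deleted2(self, profile_idx: int, j: int, k: int) -> np.ndarray:
        """ESF table with two components removed."""
        key = (profile_idx, min(j, k), max(j, k))
        cache = getattr(self, "_del2_cache", None)
        if cache is None:
            cache = self._del2_cache = {}
        if key not in cache:
            j0, k0 = key[1], key[2]
            out = np.zeros(1)
            for idx in range(len(self.model.components)):
                if idx in (j0, k0):
                    continue
                out = log_convolve(out, self.zeta[(profile_idx, idx)])
            cache[key] = out
        return cache[key]

    def pattern_prob_matrix(self, profile_idx: int, comp_idx: int) -> np.ndarray:
        """P(component pattern | R = r): matrix (R_max+1, n_patterns)."""
        comp = self.model.components[comp_idx]
        lw = self.logw[(profile_idx, comp_idx)]
        dele = self.deleted(profile_idx, comp_idx)
        lg = self.loggamma[profile_idx]
        R = lg.size - 1
        r = np.arange(R + 1)[:, None]
        sp = comp.scores[None, :]
        rem = r - sp
        ok = (rem >= 0) & (rem <= dele.size - 1)
        with np.errstate(invalid="ignore"):
            logP = np.where(ok, lw[None, :] + dele[np.clip(rem, 0, dele.size - 1)]
                            - lg[:, None], NEG_INF)
        return np.exp(logP)

    def information_matrix(self, n_by_score_per_profile: np.ndarray) -> np.ndarray:
        """Observed conditional information sum_{c,r} n_{cr} Cov(features|r,c).

        This is the exact negative Hessian of the conditional log-likelihood
        with respect to the full parameter vector; it drives both the Newton
        optimiser and the standard errors.
        """
        model = self.model
        npar = model.layout.n_params
        H = np.zeros((npar, npar))
        C = len(model.components)
        for ci in range(len(model.profiles)):
            n_r = n_by_score_per_profile[ci]
            if not n_r.any():
                continue
            Pmats = [self.pattern_prob_matrix(ci, j) for j in range(C)]
            designs = [model.design(ci, j) for j in range(C)]
            # within-component second moments
            for j in range(C):
                q = n_r @ Pmats[j]
                Mj = designs[j]
                H += (Mj.T * q) @ Mj
            # cross-component second moments
            for j in range(C):
                lwj = self.logw[(ci, j)]
                sj = model.components[j].scores
                for k in range(j + 1, C):
                    lwk = self.logw[(ci, k)]
                    sk = model.components[k].scores
                    T = self.component_score_totals(n_r, ci, j, k)
                    W = np.exp(lwj[:, None] + lwk[None, :]) * \
                        T[sj[:, None] + sk[None, :]]
                    B = designs[j].T @ W @ designs[k]
                    H += B + B.T
            # minus outer products of conditional means
            F = sum(P @ Mj for P, Mj in zip(Pmats, designs))
            H -= (F.T * n_r) @ F
        return H

    # -- item moments --------------------------------------------------------
    def item_category_probs(self, profile_idx: int = 0) -> dict:
        """P(Y_i = y | R = r) per item: dict item -> (R_max+1, m_i+1)."""
        if profile_idx in self._item_probs_cache:
            return self._item_probs_cache[profile_idx]
        out = {}
        lg = self.loggamma[profile_idx]
        R = lg.size - 1
        for ki, comp in enumerate(self.model.components):
            lw = self.logw[(profile_idx, ki)]
            dele = self.deleted(profile_idx, ki)
            r = np.arange(R + 1)[:, None]
            sp = comp.scores[None, :]
            rem = r - sp
            ok = (rem >= 0) & (rem <= dele.size - 1)
            logP = np.where(ok, lw[None, :] + dele[np.clip(rem, 0, dele.size - 1)]
                            - lg[:, None], NEG_INF)
            P = np.exp(logP)                      # (R+1, n_patterns)
            for col, it in enumerate(comp.items):
                m = self.model.max_cats[it]
                probs = np.zeros((R + 1, m + 1))
                for y in range(m + 1):
                    probs[:, y] = P[:, comp.patterns[:, col] == y].sum(axis=1)
                out[it] = probs
        self._item_probs_cache[profile_idx] = out
        return out

    def item_moments(self, profile_idx: int = 0):
        """Conditional E[Y_i | R=r] and Var[Y_i | R=r] per item."""
        probs = self.item_category_probs(profile_idx)
        E, V = {}, {}
        for it, P in probs.items():
            y = np.arange(P.shape[1])
            e = P @ y
            v = P @ (y ** 2) - e ** 2
            E[it], V[it] = e, np.maximum(v, 0.0)
        return E, V

    # -- sampling ------------------------------------------------------------
    def sample_conditional(self, rng: np.random.Generator, scores: np.ndarray,
                           profile_idx: int = 0) -> np.ndarray:
        """Draw response patterns given total scores (exact conditional draw).

        Sequential over components: the component score is drawn from
        P(s | remaining) = zeta_j[s] * suffix_{j+1}[rem - s] / suffix_j[rem],
        then the internal pattern given the component score.
        """
        scores = np.asarray(scores, dtype=np.int64)
        n = scores.size
        k = len(self.model.items)
        out = np.zeros((n, k), dtype=np.int64)
        rem = scores.copy()
        C = len(self.model.components)
        for j, comp in enumerate(self.model.components):
            suf_all = self.suffix[(profile_idx, j)]
            suf_next = self.suffix[(profile_idx, j + 1)]
            zeta = self.zeta[(profile_idx, j)]
            Rj = suf_all.size - 1
            S = comp.max_score
            r = np.arange(Rj + 1)[:, None]
            s = np.arange(S + 1)[None, :]
            remsc = r - s
            ok = (remsc >= 0) & (remsc <= suf_next.size - 1)
            logP = np.where(ok, zeta[None, :]
                            + suf_next[np.clip(remsc, 0, suf_next.size - 1)]
                            - suf_all[:, None], NEG_INF)
            cumP = np.cumsum(np.exp(logP), axis=1)
            u = rng.random(n) * cumP[rem, -1]
            s_draw = (cumP[rem] < u[:, None]).sum(axis=1)
            # internal pattern given component score
            lw = self.logw[(profile_idx, j)]
            W = np.zeros((S + 1, lw.size))
            for sc in range(S + 1):
                mask = comp.scores == sc
                w = np.zeros(lw.size)
                w[mask] = np.exp(lw[mask] - zeta[sc])
                W[sc] = w
            cumW = np.cumsum(W, axis=1)
            u2 = rng.random(n) * cumW[s_draw, -1]
            p_draw = (cumW[s_draw] < u2[:, None]).sum(axis=1)
            out[:, list(comp.item_idx)] = comp.patterns[p_draw]
            rem = rem - s_draw
        assert (rem == 0).all()
        return out

    def sample_given_theta(self, rng: np.random.Generator, theta: np.ndarray,
                           profile_idx) -> np.ndarray:
        """Draw response patterns given latent trait values.

        ``profile_idx`` may be a scalar or a per-person array.  Components
        are conditionally independent given theta.
        """
        theta = np.asarray(theta, dtype=float)
        n = theta.size
        prof = np.broadcast_to(np.asarray(profile_idx, dtype=np.int64), (n,))
        k = len(self.model.items)
        out = np.zeros((n, k), dtype=np.int64)
        for j, comp in enumerate(self.model.components):
            logits = np.empty((n, comp.patterns.shape[0]))
            for ci in np.unique(prof):
                mask = prof == ci
                lw = self.logw[(int(ci), j)]
                logits[mask] = lw[None, :] + theta[mask, None] * comp.scores[None, :]
            logits -= logits.max(axis=1, keepdims=True)
            P = np.exp(logits)
            cumP = np.cumsum(P, axis=1)
            u = rng.random(n) * cumP[:, -1]
            p_draw = (cumP < u[:, None]).sum(axis=1)
            out[:, list(comp.item_idx)] = comp.patterns[p_draw]
        return out

    # -- score distribution given theta ---------------------------------------
    def score_logpmf_given_theta(self, theta, profile_idx: int = 0) -> np.ndarray:
        """log P(R = r | theta): rows = theta values, cols = scores."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        lg = self.loggamma[profile_idx]
        r = np.arange(lg.size)
        vals = lg[None, :] + theta[:, None] * r[None, :]
        return vals - logsumexp_rows(vals)[:, None]

    def score_moments_given_theta(self, theta, profile_idx: int = 0):
        """E[R | theta] and Var[R | theta]; the variance is the test information."""
        lp = self.score_logpmf_given_theta(theta, profile_idx)
        P = np.exp(lp)
        r = np.arange(P.shape[1])
        e = P @ r
        v = P @ (r ** 2) - e ** 2
        return e, np.maximum(v, 1e-300)


# ---------------------------------------------------------------------------
# grouped sufficient statistics
# ---------------------------------------------------------------------------

class GroupedData:
    """Sufficient statistics of a sample for conditional estimation.

    Groups complete-case persons by (covariate profile, total score), keeps
    score counts and component-pattern counts, and accumulates the observed
    feature-count vector t.  Persons with extreme scores (0 or R_max)
    contribute nothing to the conditional likelihood and are excluded.
    """

    def __init__(self, model: ConditionalModel, responses: np.ndarray,
                 profile_idx: np.ndarray):
        self.model = model
        responses = np.asarray(responses)
        profile_idx = np.asarray(profile_idx, dtype=np.int64)
        complete = (responses >= 0).all(axis=1)
        scores = np.where(complete, responses.sum(axis=1), -1)
        R = model.max_score
        nonextreme = complete & (scores > 0) & (scores < R)
        self.complete = complete
        self.scores = scores
        self.nonextreme = nonextreme
        self.profile_idx = profile_idx
        self.n_used = int(nonextreme.sum())

        nprof = len(model.profiles)
        self.n_by_score = np.zeros((nprof, R + 1))
        self.pattern_counts = {}
        t = np.zeros(model.layout.n_params)
        for ci in range(nprof):
            mask = nonextreme & (profile_idx == ci)
            if mask.any():
                self.n_by_score[ci] = np.bincount(scores[mask], minlength=R + 1)
            for ki, comp in enumerate(model.components):
                sub = responses[np.ix_(mask, list(comp.item_idx))]
                # map rows to pattern indices (mixed radix)
                radix = np.ones(len(comp.items), dtype=np.int64)
                for c in range(len(comp.items) - 2, -1, -1):
                    radix[c] = radix[c + 1] * (model.max_cats[comp.items[c + 1]] + 1)
                codes = sub @ radix
                pat_codes = comp.patterns @ radix
                order = np.argsort(pat_codes)
                pos = order[np.searchsorted(pat_codes[order], codes)]
                counts = np.bincount(pos, minlength=comp.patterns.shape[0]) \
                    if codes.size else np.zeros(comp.patterns.shape[0])
                self.pattern_counts[(ci, ki)] = counts.astype(float)
                t += model.design(ci, ki).T @ self.pattern_counts[(ci, ki)]
        self.t = t

    def feature_totals(self, responses: np.ndarray,
                       profile_idx: np.ndarray) -> np.ndarray:
        """Observed feature-count vector t for a replacement response matrix
        over the same persons (rows must be complete)."""
        model = self.model
        t = np.zeros(model.layout.n_params)
        for ci in range(len(model.profiles)):
            mask = profile_idx == ci
            if not mask.any():
                continue
            for ki, comp in enumerate(model.components):
                sub = responses[np.ix_(mask, list(comp.item_idx))]
                radix = np.ones(len(comp.items), dtype=np.int64)
                for c in range(len(comp.items) - 2, -1, -1):
                    radix[c] = radix[c + 1] * \
                        (model.max_cats[comp.items[c + 1]] + 1)
                codes = sub @ radix
                pat_codes = comp.patterns @ radix
                order = np.argsort(pat_codes)
                pos = order[np.searchsorted(pat_codes[order], codes)]
                counts = np.bincount(pos, minlength=comp.patterns.shape[0])
                t += model.design(ci, ki).T @ counts.astype(float)
        return t

    def observed_category_counts(self) -> dict:
        """Observed count per (item, category) among used persons."""
        counts = {}
        for it in self.model.items:
            counts[it] = np.zeros(self.model.max_cats[it] + 1)
        for (ci, ki), pc in self.pattern_counts.items():
            comp = self.model.components[ki]
            for col, it in enumerate(comp.items):
                for y in range(self.model.max_cats[it] + 1):
                    counts[it][y] += pc[comp.patterns[:, col] == y].sum()
        return counts

    # -- likelihood / gradient --------------------------------------------
    def loglik(self, tables: ModelTables) -> float:
        ll = float(self.t @ tables.theta)
        for ci in range(len(self.model.profiles)):
            ll += tables.loglik_groups(self.n_by_score[ci], ci)
        return ll

    def score_vector(self, tables: ModelTables) -> np.ndarray:
        """Gradient of the conditional loglik w.r.t. the full parameters."""
        g = self.t.copy()
        for ci in range(len(self.model.profiles)):
            if not self.n_by_score[ci].any():
                continue
            for ki in range(len(self.model.components)):
                q = tables.expected_pattern_counts(self.n_by_score[ci], ci, ki)
                g -= self.model.design(ci, ki).T @ q
        return g
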