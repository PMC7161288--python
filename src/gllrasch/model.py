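"""Partial Credit and Graphical Log-linear Rasch models, CML-estimated.

The public surface follows the Model/Results convention: a model object is
built from a :class:`~gllrasch.data.ResponseData` (or a plain DataFrame via
:meth:`GLLRM.from_dataframe`), its :meth:`GLLRM.fit` maximises the
conditional likelihood and returns a :class:`GLLRMResults` carrying
estimates, standard errors from the observed conditional information, the
maximised conditional log-likelihood and a ``summary()`` table.

The Partial Credit model is the special case with no interaction terms::

    res = PartialCreditModel(data, items).fit()
    res = GLLRM(data, items, ld=[("item1", "item2")],
                dif=[("item1", "sex")]).fit()

Uniform LD and uniform DIF interaction parameters are constant across the
latent trait by construction; sufficiency of the total score is retained
within the DIF-defined subgroups.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .cml import ConditionalModel, GroupedData, ModelTables, model_dof
from .data import MISSING, ResponseData, ScaleSpec


class ConvergenceError(RuntimeError):
    """CML optimisation failed to reach the gradient tolerance."""


class LDSpec(tuple):
    """Set of unordered item pairs declared locally dependent."""

    def __new__(cls, pairs=()):
        norm = []
        seen = set()
        for p in pairs:
            i, j = tuple(p)
            if i == j:
                raise ValueError(f"LD pair with identical items: {i!r}")
            key = frozenset((i, j))
            if key in seen:
                raise ValueError(f"repeated LD pair {p!r}")
            seen.add(key)
            norm.append((i, j))
        return super().__new__(cls, norm)


class DIFSpec(tuple):
    """Set of (item, covariate) pairs declared to exhibit uniform DIF."""

    def __new__(cls, terms=()):
        norm = [(it, cov) for it, cov in terms]
        if len(set(norm)) != len(norm):
            raise ValueError("repeated DIF term")
        return super().__new__(cls, norm)


class GLLRM:
    """Graphical log-linear Rasch model for ordinal items.

    Parameters
    ----------
    data : ResponseData
        Responses and covariates.
    items : sequence of str, optional
        Analysis item set (defaults to every item in the data).
    ld : sequence of (item, item)
        Locally dependent pairs (uniform interaction grids).
    dif : sequence of (item, covariate)
        Uniform DIF terms.

    Notes
    -----
    Estimation is conditional on total scores, so persons with extreme
    scores carry no information about item parameters.  Categories never
    observed in the estimation sample cannot be identified under CML; such
    items are collapsed onto their observed categories for estimation and
    the missing thresholds flagged as non-estimable.
    """

    def __init__(self, data: ResponseData, items=None, ld=(), dif=()):
        self.data = data
        self.item_names = tuple(items) if items is not None else data.items
        self.ld = LDSpec(ld)
        self.dif = DIFSpec(dif)
        for it, cov in self.dif:
            if cov not in data.covariates.columns:
                raise ValueError(f"DIF covariate {cov!r} not in data")
            if it not in self.item_names:
                raise ValueError(f"DIF item {it!r} not in analysis set")
        cov_levels = {cov: data.covariate_levels[cov] for _, cov in self.dif}

        raw = data.matrix(self.item_names)
        complete = (raw != MISSING).all(axis=1)
        if not complete.any():
            raise ValueError("no complete cases for the requested item set")

        # --- null-category handling: collapse to observed categories -----
        self.category_maps = {}
        self.null_categories = {}
        work_cats = {}
        work = raw.copy()
        for col, it in enumerate(self.item_names):
            m = data.spec.max_category(it)
            vals = raw[complete, col]
            observed = np.flatnonzero(np.bincount(vals, minlength=m + 1))
            if observed.size < 2:
                raise ValueError(
                    f"item {it!r} shows responses in fewer than two categories")
            nulls = sorted(set(range(m + 1)) - set(observed.tolist()))
            self.null_categories[it] = nulls
            if nulls:
                remap = np.full(m + 1, -1, dtype=np.int64)
                remap[observed] = np.arange(observed.size)
                ok = work[:, col] != MISSING
                work[ok, col] = remap[work[ok, col]]
                self.category_maps[it] = {int(o): int(remap[o]) for o in observed}
            work_cats[it] = int(len(observed)) - 1

        self.responses_work = work
        self.work_cats = work_cats
        self.cmodel = ConditionalModel(self.item_names, work_cats,
                                       ld_pairs=self.ld, dif_terms=self.dif,
                                       cov_levels=cov_levels or None)
        self.profile_idx = self.cmodel.profile_indices(data.covariates)
        if self.cmodel.dif_covs:
            has_cov = np.ones(len(data.person_id), dtype=bool)
            for g in self.cmodel.dif_covs:
                has_cov &= data.covariates[g].notna().to_numpy()
            if not has_cov.all():
                work = work.copy()
                work[~has_cov] = MISSING          # drop persons missing a DIF covariate
                self.responses_work = work
        self.grouped = GroupedData(self.cmodel, self.responses_work,
                                   self.profile_idx)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, items, *, covariates=(),
                       covariate_levels=None, n_categories=5, ld=(), dif=(),
                       name="scale"):
        """Build directly from a 0-based coded DataFrame (NaN = missing)."""
        spec = ScaleSpec(name, tuple(items), n_categories=n_categories)
        resp = df[list(items)].copy()
        resp = resp.where(resp.notna(), MISSING).astype(np.int64)
        cov = df[list(covariates)].copy() if covariates else None
        data = ResponseData(
            person_id=np.arange(len(df)), responses=resp, spec=spec,
            covariates=cov, covariate_levels=dict(covariate_levels or {}))
        return cls(data, items=items, ld=ld, dif=dif)

    # -- estimation --------------------------------------------------------
    def loglike_full(self, theta_full) -> float:
        """Conditional log-likelihood at a full parameter vector."""
        return self.grouped.loglik(self.cmodel.tables(np.asarray(theta_full)))

    def fit(self, start=None, gtol=1e-6, maxiter=100, se=True) -> "GLLRMResults":
        """Maximise the conditional likelihood by damped Newton iteration.

        The gradient is the observed-minus-expected feature count; the
        Hessian is the exact observed conditional information (feature
        covariance given scores and profiles).  The conditional likelihood
        is concave in this parameterisation, so Newton steps with halving
        converge quickly.  Convergence requires the max-norm of the
        per-person score to fall below ``gtol``.  Standard errors come from
        the inverse information at the optimum.
        """
        lay = self.cmodel.layout
        na = lay.n_alpha
        estimable = np.ones(lay.n_params, dtype=bool)
        estimable[na:] = self.grouped.t[na:] > 0      # freeze empty margins
        self.estimable = estimable
        J = lay.jacobian(estimable)
        n = max(self.grouped.n_used, 1)

        if start is None:
            u = np.zeros(J.shape[1])
        else:
            u = lay.free_from_full(np.asarray(start), estimable)

        theta = lay.full_from_free(u, estimable)
        tabs = self.cmodel.tables(theta)
        ll = self.grouped.loglik(tabs)
        gmax = np.inf
        H_u = None
        n_iter = 0
        for n_iter in range(1, maxiter + 1):
            g = J.T @ self.grouped.score_vector(tabs)
            gmax = float(np.abs(g).max()) / n
            if gmax <= gtol:
                break
            H_u = J.T @ tabs.information_matrix(self.grouped.n_by_score) @ J
            try:
                step = np.linalg.solve(
                    H_u + 1e-10 * n * np.eye(H_u.shape[0]), g)
            except np.linalg.LinAlgError:
                raise ConvergenceError(
                    f"singular conditional information (items={self.item_names})")
            # damped step: halve until the loglik does not decrease
            t = 1.0
            for _ in range(30):
                u_new = u + t * step
                theta_new = lay.full_from_free(u_new, estimable)
                tabs_new = self.cmodel.tables(theta_new)
                ll_new = self.grouped.loglik(tabs_new)
                if ll_new >= ll - 1e-10 * max(1.0, abs(ll)):
                    break
                t /= 2
            u, theta, tabs, ll = u_new, theta_new, tabs_new, ll_new
        if gmax > gtol * 50 and gmax > 1e-5:
            raise ConvergenceError(
                f"CML estimation did not converge: max|score|/n = {gmax:.3e} "
                f"after {n_iter} iterations (items={self.item_names})")

        cov_full = bse_full = None
        if se:
            if H_u is None or gmax > 0:
                H_u = J.T @ tabs.information_matrix(self.grouped.n_by_score) @ J
            try:
                cov_u = np.linalg.inv(H_u)
            except np.linalg.LinAlgError:
                cov_u = np.linalg.pinv(H_u)
            cov_full = J @ cov_u @ J.T
            with np.errstate(invalid="ignore"):
                bse_full = np.sqrt(np.maximum(np.diag(cov_full), 0.0))
            bse_full[~estimable] = np.nan

        return GLLRMResults(self, theta, llf=ll, converged=gmax <= max(gtol * 50, 1e-5),
                            bse_full=bse_full, cov_full=cov_full,
                            estimable=estimable, n_iter=n_iter)


class PartialCreditModel(GLLRM):
    """Polytomous Rasch (Partial Credit) model: a GLLRM with no interactions."""

    def __init__(self, data: ResponseData, items=None):
        super().__init__(data, items=items, ld=(), dif=())


class GLLRMResults:
    """Fitted conditional-likelihood estimates of a (GLL)RM.

    Attributes
    ----------
    params : pandas.Series
        Estimates indexed by parameter name tuples.
    bse : pandas.Series
        Standard errors (NaN for cells frozen at zero).
    llf : float
        Maximised conditional log-likelihood.
    df_model : int
        Number of free parameters actually estimated.
    """

    def __init__(self, model: GLLRM, theta_full, llf, converged, bse_full=None,
                 cov_full=None, estimable=None, n_iter=0):
        self.model = model
        self.cmodel = model.cmodel
        self.theta_full = np.asarray(theta_full, dtype=float)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.bse_full = bse_full
        self.cov_full = cov_full
        self.estimable = estimable if estimable is not None else \
            np.ones(self.cmodel.layout.n_params, dtype=bool)
        self.n_iter = n_iter
        self.nobs = model.data.n
        self.n_used = model.grouped.n_used
        self._tables = None

    # -- parameter views ---------------------------------------------------
    @property
    def df_model(self) -> int:
        return model_dof(self.cmodel, self.estimable)

    @property
    def params(self) -> pd.Series:
        idx = pd.Index([str(nm) for nm in self.cmodel.layout.names])
        return pd.Series(self.theta_full, index=idx, name="estimate")

    @property
    def bse(self) -> pd.Series:
        idx = pd.Index([str(nm) for nm in self.cmodel.layout.names])
        vals = self.bse_full if self.bse_full is not None \
            else np.full(self.cmodel.layout.n_params, np.nan)
        return pd.Series(vals, index=idx, name="se")

    def alpha(self, item: str) -> np.ndarray:
        """Item-category parameters alpha^i_y, y = 0..m_i (working scale)."""
        return self.cmodel.layout.alpha_array(self.theta_full, item)

    def alpha_table(self) -> pd.DataFrame:
        """Tidy alpha table on the original category coding.

        Categories collapsed away because they were never observed appear
        with NaN estimates and ``estimable = False``.
        """
        rows = []
        for it in self.cmodel.items:
            m_orig = self.model.data.spec.max_category(it)
            amap = self.model.category_maps.get(it)
            a = self.alpha(it)
            se = self._se_for_item(it)
            for y in range(m_orig + 1):
                if amap is None:
                    wy, est = y, True
                elif y in amap:
                    wy, est = amap[y], True
                else:
                    wy, est = None, False
                rows.append({
                    "item": it, "category": y,
                    "alpha": a[wy] if est else np.nan,
                    "se": (se[wy] if est and wy > 0 else
                           (0.0 if est and wy == 0 else np.nan)),
                    "estimable": est,
                })
        return pd.DataFrame(rows)

    def _se_for_item(self, item):
        m = self.cmodel.max_cats[item]
        out = np.zeros(m + 1)
        if self.bse_full is None:
            out[:] = np.nan
            return out
        for y in range(1, m + 1):
            out[y] = self.bse_full[self.cmodel.layout.index[("alpha", item, y)]]
        return out

    def lambda_table(self) -> pd.DataFrame:
        rows = []
        for k, nm in enumerate(self.cmodel.layout.names):
            if nm[0] != "lambda":
                continue
            rows.append({"item_i": nm[1], "item_j": nm[2], "y_i": nm[3],
                         "y_j": nm[4], "lam": self.theta_full[k],
                         "se": self.bse_full[k] if self.bse_full is not None
                         else np.nan,
                         "estimable": bool(self.estimable[k])})
        return pd.DataFrame(rows)

    def delta_table(self) -> pd.DataFrame:
        rows = []
        for k, nm in enumerate(self.cmodel.layout.names):
            if nm[0] != "delta":
                continue
            rows.append({"item": nm[1], "covariate": nm[2], "category": nm[3],
                         "level": nm[4], "delta": self.theta_full[k],
                         "se": self.bse_full[k] if self.bse_full is not None
                         else np.nan,
                         "estimable": bool(self.estimable[k])})
        return pd.DataFrame(rows)

    def item_locations(self) -> pd.Series:
        """Item location beta_i = -alpha^i_{m_i} / m_i (sum-zero across items)."""
        locs = {}
        for it in self.cmodel.items:
            m = self.cmodel.max_cats[it]
            locs[it] = -self.alpha(it)[m] / m
        return pd.Series(locs, name="location")

    def thresholds(self, item: str) -> np.ndarray:
        """Adjacent-category thresholds tau^i_y = alpha^i_{y-1} - alpha^i_y."""
        a = self.alpha(item)
        return a[:-1] - a[1:]

    # -- model machinery ---------------------------------------------------
    def tables(self) -> ModelTables:
        if self._tables is None:
            self._tables = self.cmodel.tables(self.theta_full)
        return self._tables

    def conditional_item_moments(self, profile_idx: int = 0):
        """E[Y_i | R=r] and Var[Y_i | R=r] per item at the estimates."""
        return self.tables().item_moments(profile_idx)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        kind = "GLLRM" if (self.model.ld or self.model.dif) else \
            "Partial Credit Model"
        lines = [
            f"{kind} — conditional maximum likelihood",
            "=" * 58,
            f"items:        {', '.join(self.cmodel.items)}",
            f"n persons:    {self.nobs}  (used in CML: {self.n_used})",
            f"loglik:       {self.llf:.3f}",
            f"free params:  {self.df_model}",
            f"converged:    {self.converged}  ({self.n_iter} iterations)",
        ]
        if self.model.ld:
            lines.append("LD pairs:     " +
                         "; ".join(f"{i}~{j}" for i, j in self.model.ld))
        if self.model.dif:
            lines.append("DIF terms:    " +
                         "; ".join(f"{i}×{g}" for i, g in self.model.dif))
        lines.append("-" * 58)
        tab = self.alpha_table()
        lines.append(tab.to_string(index=False,
                                   float_format=lambda v: f"{v:8.4f}"))
        for name, t in (("Uniform LD parameters", self.lambda_table()),
                        ("Uniform DIF parameters", self.delta_table())):
            if len(t):
                lines.append("-" * 58)
                lines.append(name)
                lines.append(t.to_string(index=False,
                                         float_format=lambda v: f"{v:8.4f}"))
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Serialise structure + estimates so the model re-instantiates exactly."""
        payload = {
            "items": list(self.cmodel.items),
            "max_cats": {k: int(v) for k, v in self.cmodel.max_cats.items()},
            "ld": [list(p) for p in self.model.ld],
            "dif": [list(t) for t in self.model.dif],
            "cov_levels": {k: list(v) for k, v in self.cmodel.cov_levels.items()},
            "params": {str(nm): float(v) for nm, v in
                       zip(self.cmodel.layout.names, self.theta_full)},
            "bse": None if self.bse_full is None else
                   [None if not np.isfinite(v) else float(v)
                    for v in self.bse_full],
            "llf": self.llf,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @staticmethod
    def load_structure(path) -> ConditionalModel:
        with open(path) as fh:
            payload = json.load(fh)
        cmodel = ConditionalModel(
            payload["items"], payload["max_cats"],
            ld_pairs=[tuple(p) for p in payload["ld"]],
            dif_terms=[tuple(t) for t in payload["dif"]],
            cov_levels=payload["cov_levels"] or None)
        theta = np.array([payload["params"][str(nm)]
                          for nm in cmodel.layout.names])
        return cmodel, theta
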