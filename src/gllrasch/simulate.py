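"""Generator of PSS-14-like item-response datasets with known ground truth.

The generator emulates the response structure of a two-subscale perceived
stress instrument applied to a general-population sample: 14 five-category
items split into a negatively worded ("Perceived Stress") and a positively
worded ("Perceived Control") subscale, two correlated latent traits, sex
and education covariates with realistic prevalences, uniform LD and
uniform DIF terms with calibrated partial-gamma magnitudes, and a handful
of deliberately under-discriminating items that a stepwise item analysis
should detect and exclude.

Interaction terms are generated rank-one (lambda_{y_i y_j} = lambda0 *
y_i * y_j; delta_{y, level} = delta0 * y * level_code) so a single scalar
per term maps monotonically onto the realized partial gamma; the fitting
side still estimates the full unconstrained grids.  Under-discrimination
uses a generalized partial-credit draw P(y|theta) ~ exp(alpha_y + a*y*theta)
with a < 1 -- a generation-only device that flattens the item's observed
characteristic curve relative to Rasch expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cml import ConditionalModel
from .data import ResponseData, ScaleSpec
from .diagnostics import gamma_coefficient, partial_gamma_dif, partial_gamma_ld

# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

SEX_LEVELS = ["Male", "Female"]
EDU_LEVELS = ["UpToHighSchool", "TechnicalOrUniversity"]
#: covariate prevalences of the emulated sample (female 61.9%, tertiary 67.5%)
DEFAULT_COVARIATES = {
    "sex": (SEX_LEVELS, [0.381, 0.619]),
    "education": (EDU_LEVELS, [0.325, 0.675]),
}

STRESS_ITEMS = tuple(f"item{i}" for i in (1, 2, 3, 8, 11, 12, 14))
CONTROL_ITEMS = tuple(f"item{i}" for i in (4, 5, 6, 7, 9, 10, 13))
STRESS_FINAL = ("item1", "item2", "item3", "item11", "item14")
CONTROL_FINAL = ("item6", "item7", "item10")

#: target partial gammas of the default LD / DIF structure
TARGET_EFFECTS = {
    ("ld", "item1", "item2"): 0.18,
    ("dif", "item1", "sex"): 0.24,
    ("dif", "item3", "sex"): 0.33,
    ("dif", "item1", "education"): -0.14,
    ("ld", "item7", "item10"): 0.22,
    ("dif", "item10", "sex"): -0.23,
    ("dif", "item6", "sex"): -0.15,
    ("dif", "item10", "education"): -0.17,
}

#: rank-one interaction scalars realizing TARGET_EFFECTS (frozen calibration)
CALIBRATED_SCALARS = {
    ("ld", "item1", "item2"): 0.2846,
    ("dif", "item1", "sex"): 0.6609,
    ("dif", "item3", "sex"): 0.7875,
    ("dif", "item1", "education"): -0.2500,
    ("ld", "item7", "item10"): 0.3432,
    ("dif", "item10", "sex"): -0.8031,
    ("dif", "item6", "sex"): -0.6508,
    ("dif", "item10", "education"): -0.3053,
}

#: latent correlation of the two traits on the z scale (frozen calibration,
#: negative because raw stress and control scores run in opposite directions;
#: reverse-scoring the stress items yields the positive subscale gamma ~ 0.53)
TRAIT_CORR_Z = -0.955

#: rank-one scalars for the generic 5-item calibration scenarios
#: (frozen calibrate_effect output): LD realizing partial gamma 0.2 and
#: binary-covariate DIF realizing partial gamma 0.3
GENERIC_LD_SCALAR_02 = 0.225
GENERIC_DIF_SCALAR_03 = 0.475


def _alpha_from_location(location: float, m: int = 4, spread: float = 1.05,
                         offsets=None):
    """Item-category parameters from a location plus threshold offsets.

    With ``offsets=None`` thresholds are equally spaced (``spread`` apart)
    around the location.  The default study scenarios use asymmetric
    offsets whose upper thresholds cluster well above the population so
    the test information peaks at high trait levels -- reproducing the
    mistargeting of a general-population sample on a stress scale.
    """
    if offsets is None:
        offsets = spread * (np.arange(1, m + 1) - (m + 1) / 2)
    taus = location + np.asarray(offsets, dtype=float)
    return np.concatenate([[0.0], -np.cumsum(taus)])


@dataclass
class ItemSim:
    """Generating rules for one item."""

    name: str
    trait: str
    alpha: np.ndarray
    discrimination: float = 1.0

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha[0] != 0:
            raise ValueError("alpha[0] must be 0")
        if not self.discrimination > 0:
            raise ValueError("discrimination multiplier must be positive")

    @property
    def m(self):
        return self.alpha.size - 1


@dataclass
class SimConfig:
    """Complete description of a simulated study.

    ``trait_means``/``trait_sds`` give the base latent distribution per
    trait; ``trait_effects`` shift subgroup means additively by covariate
    level; ``trait_corr`` correlates the traits' standard-normal drivers.
    ``ld_terms``/``dif_terms`` carry rank-one interaction scalars;
    ``correlates`` are auxiliary criterion scores with a target Kendall tau
    against their trait.
    """

    n: int
    items: list
    trait_means: dict
    trait_sds: dict
    trait_corr: float = 0.0
    trait_effects: list = field(default_factory=list)   # (trait, cov, {level: shift})
    covariates: dict = field(default_factory=dict)      # name -> (levels, prev)
    ld_terms: list = field(default_factory=list)        # (item_i, item_j, lambda0)
    dif_terms: list = field(default_factory=list)       # (item, cov, delta0)
    correlates: list = field(default_factory=list)      # (name, trait, tau, sd-ish)
    reverse_for_gamma: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if not -1.0 <= self.trait_corr <= 1.0:
            raise ValueError("trait correlation must lie in [-1, 1]")
        for name, (levels, prev) in self.covariates.items():
            if abs(sum(prev) - 1.0) > 1e-9:
                raise ValueError(f"prevalences of {name!r} do not sum to 1")
            if len(levels) != len(prev):
                raise ValueError(f"levels/prevalences mismatch for {name!r}")
        names = [it.name for it in self.items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate item names")
        by_name = {it.name: it for it in self.items}
        for i, j, _ in self.ld_terms:
            if by_name[i].discrimination != 1 or by_name[j].discrimination != 1:
                raise ValueError("LD terms only on conforming items")
            if by_name[i].trait != by_name[j].trait:
                raise ValueError("LD pairs must share a trait")
        for it, cov, _ in self.dif_terms:
            if cov not in self.covariates:
                raise ValueError(f"DIF covariate {cov!r} not declared")
            if by_name[it].discrimination != 1:
                raise ValueError("DIF terms only on conforming items")

    def item(self, name):
        return next(it for it in self.items if it.name == name)

    def replace_scalar(self, term, value) -> "SimConfig":
        import copy
        cfg = copy.deepcopy(self)
        kind = term[0]
        if kind == "ld":
            terms = [(i, j, value if {i, j} == {term[1], term[2]} else s)
                     for i, j, s in cfg.ld_terms]
            if not any({i, j} == {term[1], term[2]} for i, j, _ in cfg.ld_terms):
                terms.append((term[1], term[2], value))
            cfg.ld_terms = terms
        else:
            terms = [(it, cov, value if (it, cov) == (term[1], term[2]) else s)
                     for it, cov, s in cfg.dif_terms]
            if not any((it, cov) == (term[1], term[2])
                       for it, cov, _ in cfg.dif_terms):
                terms.append((term[1], term[2], value))
            cfg.dif_terms = terms
        return cfg

    def to_yaml(self, path):
        payload = {
            "n": self.n,
            "trait_means": self.trait_means,
            "trait_sds": self.trait_sds,
            "trait_corr": self.trait_corr,
            "trait_effects": [[t, c, dict(d)] for t, c, d in self.trait_effects],
            "covariates": {k: [list(v[0]), list(map(float, v[1]))]
                           for k, v in self.covariates.items()},
            "items": [{"name": it.name, "trait": it.trait,
                       "alpha": [float(a) for a in it.alpha],
                       "discrimination": float(it.discrimination)}
                      for it in self.items],
            "ld_terms": [[i, j, float(s)] for i, j, s in self.ld_terms],
            "dif_terms": [[i, c, float(s)] for i, c, s in self.dif_terms],
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _structural_model(config: SimConfig, trait: str):
    """ConditionalModel + generating parameter vector for one trait's
    conforming items."""
    items = [it for it in config.items
             if it.trait == trait and it.discrimination == 1.0]
    if not items:
        return None, None, []
    names = [it.name for it in items]
    max_cats = {it.name: it.m for it in items}
    ld = [(i, j) for i, j, _ in config.ld_terms if i in names and j in names]
    dif = [(it, cov) for it, cov, _ in config.dif_terms if it in names]
    cov_levels = {cov: list(config.covariates[cov][0]) for _, cov in dif}
    cm = ConditionalModel(names, max_cats, ld_pairs=ld, dif_terms=dif,
                          cov_levels=cov_levels or None)
    theta = np.zeros(cm.layout.n_params)
    by_name = {it.name: it for it in items}
    for k, nm in enumerate(cm.layout.names):
        if nm[0] == "alpha":
            theta[k] = by_name[nm[1]].alpha[nm[2]]
        elif nm[0] == "lambda":
            lam0 = next(s for i, j, s in config.ld_terms
                        if {i, j} == {nm[1], nm[2]})
            theta[k] = lam0 * nm[3] * nm[4]
        elif nm[0] == "delta":
            del0 = next(s for it, cov, s in config.dif_terms
                        if (it, cov) == (nm[1], nm[2]))
            lev_code = config.covariates[nm[2]][0].index(nm[4])
            theta[k] = del0 * nm[3] * lev_code
    return cm, theta, names


def simulate_dataset(config: SimConfig, seed=None):
    """Draw a full dataset; returns (ResponseData, ground-truth dict).

    Covariates are drawn by prevalence, the latent trait pair from a
    bivariate normal, conforming items from the exact GLLRM conditional
    structure given theta and covariates, and misfitting items from the
    generalized partial-credit mechanism.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n

    cov_cols = {}
    for name, (levels, prev) in config.covariates.items():
        cov_cols[name] = rng.choice(levels, size=n, p=prev)
    cov_df = pd.DataFrame(cov_cols)

    traits = list(config.trait_means)
    rho = config.trait_corr
    z = rng.standard_normal((n, 2))
    z[:, 1] = rho * z[:, 0] + np.sqrt(max(1 - rho ** 2, 0.0)) * z[:, 1]
    theta = {}
    for t_idx, tr in enumerate(traits):
        th = config.trait_means[tr] + config.trait_sds[tr] * z[:, min(t_idx, 1)]
        for etr, cov, shifts in config.trait_effects:
            if etr != tr:
                continue
            th = th + np.vectorize(lambda lev: shifts.get(lev, 0.0))(cov_cols[cov])
        theta[tr] = th

    columns = {}
    for tr in traits:
        cm, gen_theta, names = _structural_model(config, tr)
        if cm is not None:
            prof = cm.profile_indices(cov_df) if cm.dif_covs else \
                np.zeros(n, dtype=np.int64)
            resp = cm.tables(gen_theta).sample_given_theta(rng, theta[tr], prof)
            for c, name in enumerate(names):
                columns[name] = resp[:, c]
        for it in config.items:
            if it.trait != tr or it.discrimination == 1.0:
                continue
            y = np.arange(it.m + 1)
            logits = it.alpha[None, :] + \
                it.discrimination * y[None, :] * theta[tr][:, None]
            logits -= logits.max(axis=1, keepdims=True)
            P = np.exp(logits)
            cum = np.cumsum(P, axis=1)
            u = rng.random(n) * cum[:, -1]
            columns[it.name] = (cum < u[:, None]).sum(axis=1)

    order = [it.name for it in config.items]
    resp_df = pd.DataFrame({name: columns[name] for name in order})
    spec = ScaleSpec("simulated", tuple(order),
                     reverse_scored=frozenset(config.reverse_for_gamma),
                     n_categories={it.name: it.m + 1 for it in config.items})
    cov_levels = {name: list(levels)
                  for name, (levels, _) in config.covariates.items()}
    data = ResponseData(np.arange(n), resp_df, spec, covariates=cov_df,
                        covariate_levels=cov_levels)

    correlates = {}
    for name, tr, tau, *rest in config.correlates:
        rho_c = np.sin(np.pi * np.clip(tau, -0.99, 0.99) / 2)
        zc = (theta[tr] - np.mean(theta[tr])) / np.std(theta[tr])
        correlates[name] = rho_c * zc + np.sqrt(1 - rho_c ** 2) * \
            rng.standard_normal(n)

    ground_truth = {
        "config": config,
        "theta": theta,
        "correlates": pd.DataFrame(correlates) if correlates else None,
    }
    return data, ground_truth


# ---------------------------------------------------------------------------
# effect-size calibration
# ---------------------------------------------------------------------------

def realized_effect(config: SimConfig, term, n: int = 120_000, seed: int = 77):
    """Realized partial gamma of one structural term at large n."""
    cfg = SimConfig(**{**config.__dict__, "n": n}) if config.n != n else config
    data, _ = simulate_dataset(cfg, seed=seed)
    kind = term[0]
    by_name = {it.name: it for it in config.items}
    if kind == "ld":
        trait = by_name[term[1]].trait
        item_set = [it.name for it in config.items
                    if it.trait == trait and it.discrimination == 1.0]
        return partial_gamma_ld(data, term[1], term[2], item_set).gamma
    trait = by_name[term[1]].trait
    item_set = [it.name for it in config.items
                if it.trait == trait and it.discrimination == 1.0]
    return partial_gamma_dif(data, term[1], term[2], item_set).gamma


def calibrate_effect(config: SimConfig, term, target_gamma: float,
                     n: int = 120_000, tol: float = 0.01, seed: int = 77,
                     max_iter: int = 40):
    """Scalar interaction magnitude whose realized partial gamma hits a target.

    Bisection on the rank-one scalar against the large-sample realized
    partial gamma, using common random numbers so the map is smooth and
    monotone.  Raises if the target is unreachable within the bracket.
    """
    if abs(target_gamma) >= 1:
        raise ValueError("target partial gamma must lie strictly in (-1, 1)")
    if target_gamma == 0.0:
        return 0.0

    def realized(s):
        return realized_effect(config.replace_scalar(term, s), term,
                               n=n, seed=seed)

    lo, hi = (0.0, 0.8) if target_gamma > 0 else (-0.8, 0.0)
    f_lo, f_hi = realized(lo), realized(hi)
    for _ in range(4):
        if target_gamma > 0 and f_hi < target_gamma:
            hi *= 2
            f_hi = realized(hi)
        elif target_gamma < 0 and f_lo > target_gamma:
            lo *= 2
            f_lo = realized(lo)
        else:
            break
    if not (min(f_lo, f_hi) - tol <= target_gamma <= max(f_lo, f_hi) + tol):
        raise ValueError(f"target gamma {target_gamma} unreachable in bracket")
    for _ in range(max_iter):
        mid = (lo + hi) / 2
        f_mid = realized(mid)
        if abs(f_mid - target_gamma) <= tol:
            return mid
        if (f_mid < target_gamma) == (f_lo < target_gamma):
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    return (lo + hi) / 2


def measure_realized_structure(data: ResponseData, ground_truth) -> pd.DataFrame:
    """Realized vs target effect sizes, subscale gamma, and prevalences."""
    config: SimConfig = ground_truth["config"]
    by_name = {it.name: it for it in config.items}
    rows = []
    for i, j, s in config.ld_terms:
        trait = by_name[i].trait
        item_set = [it.name for it in config.items
                    if it.trait == trait and it.discrimination == 1.0]
        g = partial_gamma_ld(data, i, j, item_set).gamma
        rows.append({"kind": "ld", "term": f"{i}~{j}", "scalar": s,
                     "target": TARGET_EFFECTS.get(("ld", i, j), np.nan),
                     "realized": g})
    for it, cov, s in config.dif_terms:
        trait = by_name[it].trait
        item_set = [x.name for x in config.items
                    if x.trait == trait and x.discrimination == 1.0]
        g = partial_gamma_dif(data, it, cov, item_set).gamma
        rows.append({"kind": "dif", "term": f"{it}×{cov}", "scalar": s,
                     "target": TARGET_EFFECTS.get(("dif", it, cov), np.nan),
                     "realized": g})
    traits = list(config.trait_means)
    if len(traits) == 2:
        from .data import apply_reverse_scoring, total_scores
        aligned = apply_reverse_scoring(data)
        sets = {tr: [it.name for it in config.items
                     if it.trait == tr and it.discrimination == 1.0]
                for tr in traits}
        sa = total_scores(aligned, sets[traits[0]])
        sb = total_scores(aligned, sets[traits[1]])
        both = sa.valid & sb.valid
        g = gamma_coefficient(sa.scores[both], sb.scores[both]).gamma
        rows.append({"kind": "dimensionality", "term": "between-subscale",
                     "scalar": config.trait_corr, "target": 0.527,
                     "realized": g})
    for name, (levels, prev) in config.covariates.items():
        for lev, p in zip(levels, prev):
            rows.append({"kind": "prevalence", "term": f"{name}={lev}",
                         "scalar": np.nan, "target": p,
                         "realized": float(np.mean(
                             data.covariates[name].to_numpy() == lev))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenario constructors (the emulated study conditions)
# ---------------------------------------------------------------------------

#: item locations: stress items sit above the population mean (low mean
#: scores, right-shifted targeting); control items even further off-target
STRESS_LOCATIONS = {"item1": 0.35, "item2": 0.55, "item3": 0.25,
                    "item11": 0.50, "item14": 0.45,
                    "item8": 0.45, "item12": 0.10}
CONTROL_LOCATIONS = {"item6": 0.55, "item7": 0.70, "item10": 0.65,
                     "item4": 0.45, "item5": 0.55, "item9": 0.50,
                     "item13": 0.40}
#: generation-only discrimination multipliers of the misfitting items;
#: strong enough that pairwise interaction terms cannot absorb the
#: flattened characteristic curves, so the exclusion loop is exercised
MISFIT_DISCRIMINATION = {"item12": 0.40, "item8": 0.72,
                         "item9": 0.40, "item13": 0.42,
                         "item4": 0.45, "item5": 0.40}
STRESS_DIST = {"mean": -0.55, "sd": 1.05}
CONTROL_DIST = {"mean": -0.50, "sd": 0.80}
#: threshold offsets: wide lower steps, clustered hard upper steps, so the
#: information function peaks ~2 SD above the population mean
STRESS_OFFSETS = (-3.2, -1.2, 1.9, 2.15)
CONTROL_OFFSETS = (-2.0, -0.7, 1.3, 1.6)
#: subgroup latent shifts (female higher stress; tertiary higher control)
TRAIT_EFFECTS = [
    ("stress", "sex", {"Female": 0.26}),
    ("control", "education", {"TechnicalOrUniversity": 0.22}),
]


def _items_for(names, locations, trait):
    offsets = STRESS_OFFSETS if trait == "stress" else CONTROL_OFFSETS
    return [ItemSim(nm, trait,
                    _alpha_from_location(locations[nm], offsets=offsets),
                    MISFIT_DISCRIMINATION.get(nm, 1.0)) for nm in names]


def _terms_for(names):
    ld = [(i, j, CALIBRATED_SCALARS[("ld", i, j)])
          for (k, i, j) in TARGET_EFFECTS if k == "ld"
          and i in names and j in names]
    dif = [(it, cov, CALIBRATED_SCALARS[("dif", it, cov)])
           for (k, it, cov) in TARGET_EFFECTS if k == "dif" and it in names]
    return ld, dif


def pss14_sim_config(n: int = 3857, seed: int = 0) -> SimConfig:
    """The default 14-item scenario: full structure, misfit items included."""
    items = _items_for(STRESS_ITEMS, STRESS_LOCATIONS, "stress") + \
        _items_for(CONTROL_ITEMS, CONTROL_LOCATIONS, "control")
    names = [it.name for it in items]
    ld, dif = _terms_for(names)
    return SimConfig(
        n=n, items=items,
        trait_means={"stress": STRESS_DIST["mean"],
                     "control": CONTROL_DIST["mean"]},
        trait_sds={"stress": STRESS_DIST["sd"], "control": CONTROL_DIST["sd"]},
        trait_corr=TRAIT_CORR_Z,
        trait_effects=list(TRAIT_EFFECTS),
        covariates=dict(DEFAULT_COVARIATES),
        ld_terms=ld, dif_terms=dif,
        correlates=[("social_support", "stress", -0.25),
                    ("effort_reward", "stress", 0.20)],
        reverse_for_gamma=STRESS_ITEMS,
        seed=seed)


def stress_scenario(n: int = 3857, seed: int = 0,
                    decoy: bool = False) -> SimConfig:
    """The fitted Perceived-Stress structure (5 items, LD 1~2, DIF by sex and
    education), optionally plus the under-discriminating decoy item 12."""
    names = list(STRESS_FINAL) + (["item12"] if decoy else [])
    items = _items_for(names, STRESS_LOCATIONS, "stress")
    ld, dif = _terms_for(list(STRESS_FINAL))
    return SimConfig(
        n=n, items=items,
        trait_means={"stress": STRESS_DIST["mean"]},
        trait_sds={"stress": STRESS_DIST["sd"]},
        trait_effects=[e for e in TRAIT_EFFECTS if e[0] == "stress"],
        covariates=dict(DEFAULT_COVARIATES),
        ld_terms=ld, dif_terms=dif, seed=seed)


def control_scenario(n: int = 3857, seed: int = 0) -> SimConfig:
    """The fitted Perceived-Control structure (3 items, LD 7~10, DIF)."""
    items = _items_for(CONTROL_FINAL, CONTROL_LOCATIONS, "control")
    ld, dif = _terms_for(list(CONTROL_FINAL))
    return SimConfig(
        n=n, items=items,
        trait_means={"control": CONTROL_DIST["mean"]},
        trait_sds={"control": CONTROL_DIST["sd"]},
        trait_effects=[e for e in TRAIT_EFFECTS if e[0] == "control"],
        covariates=dict(DEFAULT_COVARIATES),
        ld_terms=ld, dif_terms=dif, seed=seed)


def null_pcm_config(n: int = 1000, k: int = 5, m: int = 4,
                    locations=None, sd: float = 1.2, spread: float = 1.05,
                    seed: int = 0) -> SimConfig:
    """A pure Partial Credit scenario (no LD, DIF or misfit) for calibration.

    ``spread`` is the equal threshold spacing; small values keep every
    category well populated even within score subgroups, which the
    asymptotic chi-square reference of the CLR tests requires.
    """
    if locations is None:
        locations = np.linspace(-0.5, 0.5, k)
    items = [ItemSim(f"i{j}", "t",
                     _alpha_from_location(locations[j], m=m, spread=spread))
             for j in range(k)]
    return SimConfig(
        n=n, items=items, trait_means={"t": 0.0}, trait_sds={"t": sd},
        covariates=dict(DEFAULT_COVARIATES), seed=seed)
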