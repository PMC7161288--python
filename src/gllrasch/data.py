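"""Ordinal item-response data with categorical covariates.

The central container is :class:`ResponseData`: an n x k matrix of ordered
categories (coded 0..m_i, missing allowed) together with per-person
categorical covariates such as sex or education.  Raw questionnaire files
typically code five-point Likert responses 1..5; recoding to the 0-based
internal convention happens at the I/O boundary only, so that a total score
of zero is the floor of the scale, as is conventional in Rasch measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Internal code for a missing response inside integer matrices.
MISSING: int = -1


@dataclass(frozen=True)
class ScaleSpec:
    """Item membership and scoring rules for one scale or subscale.

    Parameters
    ----------
    name : str
        Scale label.
    items : tuple of str
        Ordered item (column) names.
    reverse_scored : frozenset of str
        Items whose categories are mirrored (``y -> m - y``) before analyses
        that require all items to point in the same direction.
    n_categories : int or dict
        Number of ordered categories per item (``m_i + 1``).  A single int
        applies to every item.
    """

    name: str
    items: tuple
    reverse_scored: frozenset = frozenset()
    n_categories: object = 5

    def __post_init__(self):
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "reverse_scored", frozenset(self.reverse_scored))
        unknown = self.reverse_scored - set(self.items)
        if unknown:
            raise ValueError(f"reverse_scored items not in scale: {sorted(unknown)}")
        if len(set(self.items)) != len(self.items):
            raise ValueError("duplicate item names in scale spec")

    def max_category(self, item: str) -> int:
        """Highest category code m_i of *item*."""
        if isinstance(self.n_categories, dict):
            return int(self.n_categories[item]) - 1
        return int(self.n_categories) - 1

    def max_score(self, items=None) -> int:
        items = self.items if items is None else items
        return sum(self.max_category(i) for i in items)

    def subset(self, items) -> "ScaleSpec":
        items = tuple(items)
        missing = set(items) - set(self.items)
        if missing:
            raise ValueError(f"items not in scale: {sorted(missing)}")
        ncat = self.n_categories
        if isinstance(ncat, dict):
            ncat = {i: ncat[i] for i in items}
        return ScaleSpec(self.name, items, self.reverse_scored & set(items), ncat)

    def to_dict(self) -> dict:
        ncat = self.n_categories
        if isinstance(ncat, dict):
            ncat = {k: int(v) for k, v in ncat.items()}
        else:
            ncat = int(ncat)
        return {
            "name": self.name,
            "items": list(self.items),
            "reverse_scored": sorted(self.reverse_scored),
            "n_categories": ncat,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScaleSpec":
        return cls(
            name=d["name"],
            items=tuple(d["items"]),
            reverse_scored=frozenset(d.get("reverse_scored", ())),
            n_categories=d.get("n_categories", 5),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ScaleSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def pss14_spec() -> ScaleSpec:
    """The 14-item Perceived Stress Scale layout.

    Negatively worded items (1, 2, 3, 8, 11, 12, 14) form the "Perceived
    Stress" subscale; positively worded items (4, 5, 6, 7, 9, 10, 13) form
    "Perceived Control".  All items have five ordered categories.
    """
    return ScaleSpec(
        name="PSS-14",
        items=tuple(f"item{i}" for i in range(1, 15)),
        reverse_scored=frozenset(f"item{i}" for i in (1, 2, 3, 8, 11, 12, 14)),
        n_categories=5,
    )


PSS14_STRESS_ITEMS = tuple(f"item{i}" for i in (1, 2, 3, 8, 11, 12, 14))
PSS14_CONTROL_ITEMS = tuple(f"item{i}" for i in (4, 5, 6, 7, 9, 10, 13))


@dataclass
class ResponseData:
    """Person x item ordinal responses plus categorical covariates.

    ``responses`` holds integer category codes with :data:`MISSING` (-1) for
    missing cells.  ``covariates`` maps covariate name to a per-person array
    of string labels; ``covariate_levels`` declares the label set of each
    covariate with the first entry taken as the reference level.
    """

    person_id: np.ndarray
    responses: pd.DataFrame
    spec: ScaleSpec
    covariates: pd.DataFrame = None
    covariate_levels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.person_id = np.asarray(self.person_id)
        if len(np.unique(self.person_id)) != len(self.person_id):
            raise ValueError("person_id values must be unique")
        if self.responses.shape[0] != len(self.person_id):
            raise ValueError("responses/person_id length mismatch")
        if self.responses.shape[1] < 2:
            raise ValueError("need at least two items")
        if self.responses.shape[0] < 1:
            raise ValueError("need at least one person")
        self.responses = self.responses.astype(np.int64)
        for item in self.responses.columns:
            if item not in self.spec.items:
                raise ValueError(f"item column {item!r} not in scale spec")
            col = self.responses[item].to_numpy()
            m = self.spec.max_category(item)
            bad = (col != MISSING) & ((col < 0) | (col > m))
            if bad.any():
                raise ValueError(f"out-of-range responses for {item!r}")
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=range(len(self.person_id)))
        for cov in self.covariates.columns:
            levels = self.covariate_levels.get(cov)
            if levels is None:
                levels = sorted(self.covariates[cov].dropna().unique())
                self.covariate_levels[cov] = list(levels)
            observed = set(self.covariates[cov].dropna().unique())
            if not observed <= set(levels):
                raise ValueError(
                    f"covariate {cov!r} has values outside declared levels"
                )

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.responses.shape[0]

    @property
    def items(self):
        return tuple(self.responses.columns)

    def matrix(self, items=None) -> np.ndarray:
        """Integer response matrix (MISSING = -1) for the given items."""
        items = list(items) if items is not None else list(self.items)
        return self.responses[items].to_numpy()

    def reference_level(self, cov: str) -> str:
        return self.covariate_levels[cov][0]

    def subset_persons(self, mask) -> "ResponseData":
        mask = np.asarray(mask)
        return ResponseData(
            person_id=self.person_id[mask],
            responses=self.responses.loc[mask].reset_index(drop=True),
            spec=self.spec,
            covariates=self.covariates.loc[mask].reset_index(drop=True),
            covariate_levels=dict(self.covariate_levels),
        )

    def with_responses(self, responses: pd.DataFrame) -> "ResponseData":
        return ResponseData(
            person_id=self.person_id,
            responses=responses,
            spec=self.spec,
            covariates=self.covariates,
            covariate_levels=dict(self.covariate_levels),
        )


@dataclass
class ScoreVector:
    """Total scores over a stated item set, with complete-case validity flags."""

    scores: np.ndarray
    valid: np.ndarray
    items: tuple
    max_score: int

    def valid_scores(self) -> np.ndarray:
        return self.scores[self.valid]


def apply_reverse_scoring(data: ResponseData, spec: ScaleSpec = None) -> ResponseData:
    """Mirror reverse-scored items: ``y -> m_i - y``; missing cells preserved.

    Applying the operation twice restores the original matrix.
    """
    spec = spec or data.spec
    resp = data.responses.copy()
    for item in spec.reverse_scored:
        if item not in resp.columns:
            continue
        m = spec.max_category(item)
        col = resp[item].to_numpy()
        flipped = np.where(col == MISSING, MISSING, m - col)
        resp[item] = flipped
    return data.with_responses(resp)


def total_scores(data: ResponseData, items=None) -> ScoreVector:
    """Sum scores R = sum_i y_i; persons missing any item are flagged invalid.

    No imputation is performed: a person missing an item in the requested set
    simply does not receive a score for that set.
    """
    items = list(items) if items is not None else list(data.items)
    if not items:
        raise ValueError("empty item list")
    mat = data.matrix(items)
    valid = (mat != MISSING).all(axis=1)
    scores = np.where(valid, mat.sum(axis=1), 0)
    max_score = sum(data.spec.max_category(i) for i in items)
    return ScoreVector(scores=scores, valid=valid, items=tuple(items), max_score=max_score)


def load_responses(path, spec: ScaleSpec, covariate_names=(), *,
                   covariate_levels=None, sep=",", likert_base=1,
                   id_column="person_id") -> ResponseData:
    """Read a delimited response file and recode to 0-based categories.

    Raw codes ``likert_base .. likert_base + m_i`` map to ``0..m_i``; cells
    outside that range (or non-numeric) become missing, with the total count
    of such cells logged as a warning.
    """
    df = pd.read_csv(path, sep=sep)
    for item in spec.items:
        if item not in df.columns:
            raise ValueError(f"item column {item!r} missing from {path}")
    if id_column in df.columns:
        pid = df[id_column].to_numpy()
    else:
        pid = np.arange(len(df))
    if len(np.unique(pid)) != len(pid):
        raise ValueError("duplicated person_id in input file")

    n_bad = 0
    recoded = {}
    for item in spec.items:
        m = spec.max_category(item)
        raw = pd.to_numeric(df[item], errors="coerce").to_numpy(dtype=float)
        shifted = raw - likert_base
        out = np.full(len(df), MISSING, dtype=np.int64)
        ok = np.isfinite(shifted) & (shifted >= 0) & (shifted <= m) \
            & (shifted == np.floor(shifted))
        out[ok] = shifted[ok].astype(np.int64)
        n_bad += int((~ok & np.isfinite(raw)).sum())
        recoded[item] = out
    if n_bad:
        logger.warning("%d out-of-range response cells set to missing", n_bad)

    cov = df[list(covariate_names)].copy() if covariate_names else None
    return ResponseData(
        person_id=pid,
        responses=pd.DataFrame(recoded),
        spec=spec,
        covariates=cov,
        covariate_levels=dict(covariate_levels or {}),
    )


def write_responses(data: ResponseData, path, *, sep=",", likert_base=1) -> None:
    """Write responses (back on the raw 1-based Likert coding) plus covariates."""
    out = pd.DataFrame({"person_id": data.person_id})
    for item in data.items:
        col = data.responses[item].to_numpy()
        out[item] = np.where(col == MISSING, np.nan, col + likert_base)
    for cov in data.covariates.columns:
        out[cov] = data.covariates[cov].to_numpy()
    out.to_csv(path, sep=sep, index=False)
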