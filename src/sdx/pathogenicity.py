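"""Criteria-based variant pathogenicity.

A documented 14-criterion rule table maps a per-variant annotation bundle
to a boolean evidence profile; a logistic model maps the profile to a
probability of pathogenicity; the standard five-tier class is derived from
the triggered set with the usual combining rules.
"""

from __future__ import annotations

import functools
import io
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression

from .config import Settings, DEFAULT_SETTINGS

logger = logging.getLogger(__name__)

__all__ = [
    "CRITERIA",
    "PATHOGENIC_CRITERIA",
    "BENIGN_CRITERIA",
    "AnnotationBundle",
    "CriteriaProfile",
    "PathogenicityModel",
    "trigger_criteria",
    "pathogenicity_score",
    "acmg_class",
    "default_model",
    "fit_model",
    "synthetic_criteria_corpus",
    "save_model",
    "load_model",
]

PATHOGENIC_CRITERIA = ("PVS1", "PS1", "PS2", "PM1", "PM2", "PM4", "PP2", "PP3", "PP5")
BENIGN_CRITERIA = ("BA1", "BS1", "BS2", "BP4", "BP6")
CRITERIA: Tuple[str, ...] = PATHOGENIC_CRITERIA + BENIGN_CRITERIA

# consequences treated as null (loss-of-function) alleles
NULL_CONSEQUENCES = {
    "stop_gained",
    "frameshift_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "start_lost",
}
# consequences that change protein length without being null
LENGTH_CHANGE_CONSEQUENCES = {"inframe_insertion", "inframe_deletion", "stop_lost"}


@dataclass(frozen=True)
class AnnotationBundle:
    """Per-variant annotations feeding the criteria rule table."""

    consequence: Optional[str] = None
    population_af: Optional[float] = None
    damage_score: Optional[float] = None       # in-silico deleteriousness in [0,1]
    de_novo: Optional[bool] = None             # confirmed trio de novo
    known_classification: Optional[str] = None  # "pathogenic" | "benign" | None
    same_aa_change_pathogenic: bool = False
    in_hotspot: bool = False
    gene_lof_mechanism: bool = False
    gene_missense_constrained: bool = False
    healthy_homozygotes: int = 0


_MUTUALLY_EXCLUSIVE = (("PP3", "BP4"), ("PP5", "BP6"), ("PM2", "BA1"), ("PM2", "BS1"))


@dataclass(frozen=True)
class CriteriaProfile:
    triggered: Mapping[str, bool]

    def __post_init__(self):
        unknown = set(self.triggered) - set(CRITERIA)
        if unknown:
            raise ValueError(f"unknown criteria: {sorted(unknown)}")
        for a, b in _MUTUALLY_EXCLUSIVE:
            if self.triggered.get(a) and self.triggered.get(b):
                raise ValueError(f"criteria {a} and {b} cannot co-trigger")

    def __getitem__(self, criterion: str) -> bool:
        return bool(self.triggered.get(criterion, False))

    @property
    def triggered_set(self) -> frozenset:
        return frozenset(c for c, on in self.triggered.items() if on)

    def with_criterion(self, criterion: str, value: bool = True) -> "CriteriaProfile":
        d = dict(self.triggered)
        d[criterion] = value
        return CriteriaProfile(d)


def trigger_criteria(
    bundle: AnnotationBundle, settings: Settings = DEFAULT_SETTINGS
) -> CriteriaProfile:
    """Apply the documented rule table to an annotation bundle.

    A criterion whose mandatory annotation is missing abstains (False) with
    a logged warning; this never raises.
    """
    af = bundle.population_af
    dmg = bundle.damage_score
    csq = bundle.consequence

    out: Dict[str, bool] = {c: False for c in CRITERIA}

    if csq is None:
        logger.warning("consequence missing; PVS1/PM4/PP2 abstain")
    else:
        out["PVS1"] = csq in NULL_CONSEQUENCES and bundle.gene_lof_mechanism
        out["PM4"] = csq in LENGTH_CHANGE_CONSEQUENCES
        out["PP2"] = csq == "missense_variant" and bundle.gene_missense_constrained

    out["PS1"] = bundle.same_aa_change_pathogenic
    out["PS2"] = bundle.de_novo is True
    out["PM1"] = bundle.in_hotspot

    out["BA1"] = af is not None and af > settings.ba1_min_af
    out["BS1"] = af is not None and not out["BA1"] and af > settings.bs1_min_af
    out["PM2"] = af is None or af < settings.pm2_max_af
    out["BS2"] = bundle.healthy_homozygotes > 0

    if dmg is None:
        logger.warning("damage score missing; PP3/BP4 abstain")
    else:
        out["PP3"] = dmg >= settings.pp3_min_damage
        out["BP4"] = dmg <= settings.bp4_max_damage

    out["PP5"] = bundle.known_classification == "pathogenic"
    out["BP6"] = bundle.known_classification == "benign"

    return CriteriaProfile(out)


@dataclass(frozen=True)
class PathogenicityModel:
    weights: Mapping[str, float]
    intercept: float

    def score(self, profile: CriteriaProfile) -> float:
        z = self.intercept
        for criterion, on in profile.triggered.items():
            if criterion not in self.weights:
                raise KeyError(f"criterion {criterion} unknown to the model")
            if on:
                z += self.weights[criterion]
        return 1.0 / (1.0 + math.exp(-z))


def pathogenicity_score(profile: CriteriaProfile, model: PathogenicityModel) -> float:
    """Probability of pathogenicity: sigmoid over the triggered-criteria sum."""
    return model.score(profile)


# Log-odds used only to generate the synthetic calibration corpus; chosen so
# that very-strong > strong > moderate > supporting evidence, mirroring the
# usual evidence hierarchy.
_GENERATOR_LOGODDS: Dict[str, float] = {
    "PVS1": 6.0, "PS1": 4.5, "PS2": 4.5,
    "PM1": 2.2, "PM2": 2.2, "PM4": 2.2,
    "PP2": 1.0, "PP3": 1.0, "PP5": 1.0,
    "BA1": -6.0, "BS1": -4.5, "BS2": -4.5,
    "BP4": -1.0, "BP6": -1.0,
}
_GENERATOR_INTERCEPT = -3.0


def synthetic_criteria_corpus(
    seed: int, n: int = 6000
) -> Tuple[np.ndarray, np.ndarray]:
    """Random criteria profiles with labels drawn from a known logistic law."""
    rng = np.random.default_rng(seed)
    x = (rng.random((n, len(CRITERIA))) < 0.25).astype(float)
    # enforce the mutual-exclusion structure of real profiles
    idx = {c: i for i, c in enumerate(CRITERIA)}
    for a, b in _MUTUALLY_EXCLUSIVE:
        both = (x[:, idx[a]] > 0) & (x[:, idx[b]] > 0)
        drop_a = rng.random(n) < 0.5
        x[both & drop_a, idx[a]] = 0.0
        x[both & ~drop_a, idx[b]] = 0.0
    z = _GENERATOR_INTERCEPT + x @ np.array([_GENERATOR_LOGODDS[c] for c in CRITERIA])
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-z))).astype(int)
    return x, y


def fit_model(x: np.ndarray, y: np.ndarray) -> PathogenicityModel:
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to fit the pathogenicity model")
    clf = LogisticRegression(max_iter=2000, C=10.0)
    clf.fit(x, y)
    weights = {c: float(w) for c, w in zip(CRITERIA, clf.coef_[0])}
    return PathogenicityModel(weights=weights, intercept=float(clf.intercept_[0]))


@functools.lru_cache(maxsize=None)
def default_model(seed: int = 1234) -> PathogenicityModel:
    """Model fitted once on the seeded synthetic corpus (deterministic)."""
    x, y = synthetic_criteria_corpus(seed)
    return fit_model(x, y)


def save_model(model: PathogenicityModel, stream) -> None:
    close = False
    if isinstance(stream, str):
        stream, close = open(stream, "w"), True
    try:
        stream.write(f"intercept={model.intercept!r}\n")
        for c in CRITERIA:
            stream.write(f"{c}={model.weights[c]!r}\n")
    finally:
        if close:
            stream.close()


def load_model(stream) -> PathogenicityModel:
    if isinstance(stream, str) and "\n" not in stream and "=" not in stream:
        with open(stream) as fh:
            return load_model(fh)
    text = stream.read() if hasattr(stream, "read") else stream
    weights: Dict[str, float] = {}
    intercept = 0.0
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key = key.strip()
        if key == "intercept":
            intercept = float(value)
        elif key in CRITERIA:
            weights[key] = float(value)
        else:
            raise ValueError(f"unknown model key {key!r}")
    missing = set(CRITERIA) - set(weights)
    if missing:
        raise ValueError(f"model file missing criteria: {sorted(missing)}")
    return PathogenicityModel(weights=weights, intercept=intercept)


def acmg_class(profile: CriteriaProfile) -> str:
    """Five-tier class from the triggered set via the standard combining rules.

    Conflicting pathogenic-tier and benign-tier outcomes collapse to VUS.
    """
    on = profile.triggered_set
    pvs = "PVS1" in on
    ps = sum(1 for c in on if c.startswith("PS"))
    pm = sum(1 for c in on if c.startswith("PM"))
    pp = sum(1 for c in on if c.startswith("PP"))
    ba = "BA1" in on
    bs = sum(1 for c in on if c.startswith("BS"))
    bp = sum(1 for c in on if c.startswith("BP"))

    pathogenic = (
        (pvs and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs and pm == 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = ba or bs >= 2
    likely_benign = (bs == 1 and bp >= 1) or bp >= 2

    path_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if path_side and benign_side:
        return "VUS"
    if pathogenic:
        return "Pathogenic"
    if likely_pathogenic:
        return "Likely pathogenic"
    if benign:
        return "Benign"
    if likely_benign:
        return "Likely benign"
    return "VUS"
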