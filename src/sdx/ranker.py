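"""Candidate enumeration, feature assembly, ranking models and evaluation.

Each candidate diagnosis — a single variant or a compound-heterozygous
pair — carries exactly four features: pathogenicity probability,
phenotypic similarity, inheritance match and call quality.  Probabilistic
classifiers rank candidates per proband; leave-one-proband-out
cross-validation measures top-K recovery of the labeled causative, and
ensemble-member entropies decompose predictive uncertainty.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier

from .inheritance import (
    CompoundHetPair,
    SegregationResult,
    detect_compound_het,
    infer_segregation,
    inheritance_match,
)
from .variants import GT, Pedigree, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureVector",
    "CandidateDiagnosis",
    "RankedList",
    "TrainedRanker",
    "quality_feature",
    "enumerate_candidates",
    "assemble_features",
    "train_model",
    "rank_candidates",
    "lopo_cv",
    "cdf_at_k",
    "prediction_uncertainty",
    "binary_entropy",
]

FEATURE_NAMES = ("pathogenicity", "phenotypic_similarity", "inheritance_match", "quality")


@dataclass(frozen=True)
class FeatureVector:
    pathogenicity: float
    phenotypic_similarity: float
    inheritance_match: int
    quality: int

    def __post_init__(self):
        for name in ("pathogenicity", "phenotypic_similarity"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be finite in [0,1], got {v}")
        for name in ("inheritance_match", "quality"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.pathogenicity, self.phenotypic_similarity,
             float(self.inheritance_match), float(self.quality)]
        )


@dataclass(frozen=True)
class CandidateDiagnosis:
    proband: str
    variants: Tuple[VariantRecord, ...]     # length 1 or 2
    gene: str
    features: Optional[FeatureVector] = None
    label: str = "unknown"                  # causative | non_causative | unknown
    segregation: Optional[SegregationResult] = None
    acmg_class: Optional[str] = None
    predicted_probability: Optional[float] = None
    uncertainty_total: Optional[float] = None
    uncertainty_epistemic: Optional[float] = None
    reliability: Optional[float] = None
    rank: Optional[int] = None
    flags: frozenset = frozenset()

    def __post_init__(self):
        if len(self.variants) not in (1, 2):
            raise ValueError("a candidate holds 1 variant or a pair")
        if len(self.variants) == 2:
            genes = {v.gene for v in self.variants}
            if genes != {self.gene}:
                raise ValueError("pair variants must share the candidate's gene")
        if self.label not in ("causative", "non_causative", "unknown"):
            raise ValueError(f"bad label {self.label!r}")

    @property
    def is_pair(self) -> bool:
        return len(self.variants) == 2

    @property
    def sort_coordinate(self) -> Tuple[str, int]:
        v = min(self.variants, key=lambda r: (r.chrom, r.pos))
        return (v.chrom, v.pos)

    @property
    def variant_ids(self) -> str:
        return "|".join(f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}" for v in self.variants)


@dataclass(frozen=True)
class RankedList:
    proband: str
    candidates: Tuple[CandidateDiagnosis, ...]

    def __post_init__(self):
        ranks = [c.rank for c in self.candidates]
        if ranks != list(range(1, len(self.candidates) + 1)):
            raise ValueError("ranks must be 1..N in order")

    def causative_rank(self) -> Optional[int]:
        ranks = [c.rank for c in self.candidates if c.label == "causative"]
        return min(ranks) if ranks else None


def quality_feature(record: VariantRecord, missing_is_pass: bool = False) -> int:
    """1 for a (case-insensitive) PASS FILTER, 0 for anything else.

    A missing FILTER (".") counts as non-PASS unless configured otherwise.
    """
    filt = (record.filter_field or ".").strip()
    if filt == ".":
        return 1 if missing_is_pass else 0
    return 1 if filt.upper() == "PASS" else 0


def enumerate_candidates(
    records: Sequence[VariantRecord],
    pedigree: Pedigree,
    known_genes: Set[str],
) -> List[CandidateDiagnosis]:
    """Singleton candidates on annotated genes plus compound-het pairs."""
    singles = [
        CandidateDiagnosis(proband=pedigree.proband, variants=(r,), gene=r.gene)
        for r in records
        if r.gene is not None and r.gene in known_genes
    ]
    by_gene: Dict[str, List[VariantRecord]] = {}
    for c in singles:
        by_gene.setdefault(c.gene, []).append(c.variants[0])
    pairs: List[CandidateDiagnosis] = []
    for gene in sorted(by_gene):
        for pair in detect_compound_het(by_gene[gene], pedigree):
            pairs.append(
                CandidateDiagnosis(
                    proband=pedigree.proband,
                    variants=(pair.first, pair.second),
                    gene=gene,
                    flags=pair.flags,
                )
            )
    return singles + pairs


def assemble_features(
    candidate: CandidateDiagnosis,
    phenotypic_similarity: float,
    pathogenicity_by_variant: Mapping[Tuple[str, int, str, str], float],
    pedigree: Pedigree,
    expected_moi: Optional[Set[str]],
    missing_is_pass: bool = False,
) -> CandidateDiagnosis:
    """Fill the four-feature vector and segregation result for a candidate.

    Pairs aggregate conservatively: pathogenicity is the minimum of the two
    variant scores and quality the logical AND; the similarity is the shared
    gene's score; the segregation pattern is compound-het by construction.
    """
    try:
        path_scores = [pathogenicity_by_variant[v.key] for v in candidate.variants]
    except KeyError as exc:
        raise KeyError(f"missing pathogenicity score for variant {exc}") from exc

    quality = min(quality_feature(v, missing_is_pass) for v in candidate.variants)
    if candidate.is_pair:
        seg = SegregationResult(
            "ar_compound_het", candidate.variants[0].context,
            flags=candidate.flags,
        )
    else:
        v = candidate.variants[0]
        seg = infer_segregation(v.genotypes, pedigree, v.context)
    match = 1 if inheritance_match(seg, expected_moi) else 0
    fv = FeatureVector(
        pathogenicity=min(path_scores),
        phenotypic_similarity=phenotypic_similarity,
        inheritance_match=match,
        quality=quality,
    )
    return replace(candidate, features=fv, segregation=seg)


@dataclass
class TrainedRanker:
    kind: str
    clf: object
    seed: int

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        proba = self.clf.predict_proba(x)
        pos = list(self.clf.classes_).index(1)
        return proba[:, pos]

    def member_probabilities(self, x: np.ndarray) -> np.ndarray:
        """Per-weak-classifier probabilities, shape (n, n_members).

        Only the ensemble exposes multiple members; other model kinds return
        a single column (their uncertainty is purely aleatoric).
        """
        if self.kind == "ensemble":
            cols = []
            for est in self.clf.estimators_:
                proba = est.predict_proba(x)
                pos = list(est.classes_).index(1)
                cols.append(proba[:, pos])
            return np.column_stack(cols)
        return self.predict_proba(x).reshape(-1, 1)


def _make_classifier(kind: str, seed: int):
    if kind == "ensemble":
        return RandomForestClassifier(
            n_estimators=100,
            class_weight="balanced",
            random_state=seed,
            n_jobs=1,
        )
    if kind == "linear":
        return LogisticRegression(
            class_weight="balanced", max_iter=1000, random_state=seed
        )
    if kind == "bayes":
        return GaussianNB()
    if kind == "mlp":
        return MLPClassifier(hidden_layer_sizes=(16,), max_iter=800, random_state=seed)
    raise ValueError(f"unknown model kind {kind!r}")


def _design_matrix(candidates: Sequence[CandidateDiagnosis]) -> np.ndarray:
    missing = [c.variant_ids for c in candidates if c.features is None]
    if missing:
        raise ValueError(f"candidates without features: {missing[:3]}")
    return np.vstack([c.features.as_array() for c in candidates])


def train_model(
    candidates: Sequence[CandidateDiagnosis], model_kind: str = "ensemble", seed: int = 0
) -> TrainedRanker:
    """Fit a probabilistic ranker on labeled candidates.

    Class imbalance is handled by inverse-frequency class weighting where
    the estimator supports it; training is deterministic given the seed.
    """
    labeled = [c for c in candidates if c.label in ("causative", "non_causative")]
    x = _design_matrix(labeled)
    y = np.array([1 if c.label == "causative" else 0 for c in labeled])
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    clf = _make_classifier(model_kind, seed)
    clf.fit(x, y)
    return TrainedRanker(kind=model_kind, clf=clf, seed=seed)


def rank_candidates(
    model: TrainedRanker, candidates: Sequence[CandidateDiagnosis]
) -> RankedList:
    """Order candidates by predicted probability, descending.

    Ties break by pathogenicity desc, phenotypic similarity desc, genomic
    coordinate asc; ranks are assigned 1..N.
    """
    if not candidates:
        raise ValueError("no candidates to rank")
    x = _design_matrix(candidates)
    probs = model.predict_proba(x)
    members = model.member_probabilities(x)
    enriched = []
    for c, p, mem in zip(candidates, probs, members):
        total, _, epistemic = prediction_uncertainty(mem)
        enriched.append(
            replace(
                c,
                predicted_probability=float(p),
                uncertainty_total=total,
                uncertainty_epistemic=epistemic,
            )
        )
    enriched.sort(
        key=lambda c: (
            -c.predicted_probability,
            -c.features.pathogenicity,
            -c.features.phenotypic_similarity,
            c.sort_coordinate,
        )
    )
    ranked = tuple(replace(c, rank=i + 1) for i, c in enumerate(enriched))
    return RankedList(proband=candidates[0].proband, candidates=ranked)


@dataclass(frozen=True)
class LopoResult:
    causative_ranks: Dict[str, int]
    n_models: int
    ranked_lists: Dict[str, RankedList]


def lopo_cv(
    cohort: Mapping[str, Sequence[CandidateDiagnosis]],
    model_kind: str = "ensemble",
    seed: int = 0,
) -> LopoResult:
    """Leave-one-proband-out cross-validation.

    For each proband, a model is trained on every other proband's labeled
    candidates and the held-out proband's candidates are ranked; the rank
    of its causative is recorded.  Probands without a labeled causative are
    excluded with a warning.
    """
    usable = {
        pid: cands
        for pid, cands in cohort.items()
        if any(c.label == "causative" for c in cands)
    }
    for pid in cohort:
        if pid not in usable:
            logger.warning("proband %s has no labeled causative; excluded", pid)
    if len(usable) < 2:
        raise ValueError("LOPO CV needs at least two probands with causatives")

    ranks: Dict[str, int] = {}
    lists: Dict[str, RankedList] = {}
    n_models = 0
    for pid in sorted(usable):
        train = [c for other, cands in usable.items() if other != pid for c in cands]
        model = train_model(train, model_kind=model_kind, seed=seed)
        n_models += 1
        ranked = rank_candidates(model, list(usable[pid]))
        lists[pid] = ranked
        ranks[pid] = ranked.causative_rank()
    return LopoResult(causative_ranks=ranks, n_models=n_models, ranked_lists=lists)


def cdf_at_k(ranks: Sequence[int], k: int) -> float:
    """Fraction of cases whose causative rank is within the top k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranks = list(ranks)
    if not ranks:
        raise ValueError("empty rank list")
    return sum(1 for r in ranks if r <= k) / len(ranks)


def binary_entropy(p: float) -> float:
    """Shannon entropy of a Bernoulli(p), in bits."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0,1]")
    if p in (0.0, 1.0):
        return 0.0
    return -(p * math.log2(p) + (1.0 - p) * math.log2(1.0 - p))


def prediction_uncertainty(
    member_probabilities: Sequence[float],
) -> Tuple[float, float, float]:
    """(total, aleatoric, epistemic) uncertainty in bits.

    Total is the entropy of the mean member probability; aleatoric the mean
    of member entropies; epistemic their difference (non-negative by
    Jensen's inequality, clipped against rounding).
    """
    probs = [float(p) for p in member_probabilities]
    if not probs:
        raise ValueError("need at least one member probability")
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0,1]")
    total = binary_entropy(sum(probs) / len(probs))
    aleatoric = sum(binary_entropy(p) for p in probs) / len(probs)
    epistemic = max(total - aleatoric, 0.0)
    return total, aleatoric, epistemic
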