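"""Family segregation inference under complete penetrance.

Assigns each candidate a segregation pattern from the family genotypes
(de novo, recessive homozygous, compound heterozygous, isodisomy,
X-linked hemizygous recessive, Y-linked, inherited dominant), pairs
trans-configured heterozygous variants within a gene, and matches the
inferred pattern against the gene's expected mode of inheritance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

from .variants import GT, Pedigree, PedigreeMember, VariantRecord

__all__ = [
    "MOI_CODES",
    "SegregationResult",
    "CompoundHetPair",
    "infer_segregation",
    "detect_compound_het",
    "inheritance_match",
    "normalize_moi",
    "parental_origin",
]

MOI_CODES = ("AD", "AR", "XLD", "XLR", "YL", "MT")

# free-text mode-of-inheritance labels normalized to the 6 codes
_MOI_SYNONYMS = {
    "autosomal dominant": "AD",
    "autosomal dominant inheritance": "AD",
    "ad": "AD",
    "autosomal recessive": "AR",
    "autosomal recessive inheritance": "AR",
    "ar": "AR",
    "x-linked dominant": "XLD",
    "x-linked dominant inheritance": "XLD",
    "xld": "XLD",
    "x-linked recessive": "XLR",
    "x-linked recessive inheritance": "XLR",
    "x-linked": "XLR",
    "xlr": "XLR",
    "y-linked": "YL",
    "y-linked inheritance": "YL",
    "yl": "YL",
    "mitochondrial": "MT",
    "mitochondrial inheritance": "MT",
    "mt": "MT",
}


def normalize_moi(label: str) -> Optional[str]:
    return _MOI_SYNONYMS.get(label.strip().lower())


@dataclass(frozen=True)
class SegregationResult:
    pattern: str                      # one of the pattern names below
    chromosome_context: str           # autosomal | chrX | chrY
    flags: FrozenSet[str] = frozenset()

    PATTERNS = (
        "de_novo",
        "ar_homozygous",
        "ar_compound_het",
        "x_linked_recessive_hemi",
        "isodisomy",
        "y_linked",
        "dominant_inherited",
        "unknown",
    )

    def __post_init__(self):
        if self.pattern not in self.PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.pattern == "y_linked" and self.chromosome_context != "chrY":
            raise ValueError("y_linked requires chrY context")
        if self.pattern == "x_linked_recessive_hemi" and self.chromosome_context != "chrX":
            raise ValueError("x_linked_recessive_hemi requires chrX context")


@dataclass(frozen=True)
class CompoundHetPair:
    first: VariantRecord
    second: VariantRecord
    origins: Tuple[str, str]          # maternal | paternal | de_novo | ambiguous | unknown
    flags: FrozenSet[str] = frozenset()


class SegregationError(ValueError):
    pass


def _is_recessive_genotype(g: GT, sex: str, context: str) -> bool:
    """Genotype sufficient for disease under a recessive model."""
    if context == "chrX" and sex == "male":
        return g in (GT.HEMI, GT.HOM_ALT)
    if context == "chrY":
        return g in (GT.HEMI, GT.HOM_ALT)
    return g == GT.HOM_ALT


def _genotype(genotypes: Mapping[str, GT], sample: Optional[str]) -> Optional[GT]:
    if sample is None:
        return None
    g = genotypes.get(sample, GT.MISSING)
    return None if g is GT.MISSING else g


def infer_segregation(
    genotypes: Mapping[str, GT],
    pedigree: Pedigree,
    chromosome_context: str = "autosomal",
) -> SegregationResult:
    """Classify one candidate's segregation pattern under complete penetrance.

    All affected members must share the triggering genotype and no genotyped
    healthy member may carry a genotype sufficient for disease under the
    assigned pattern; otherwise the pattern is ``unknown``.  With no parental
    genotypes the inference falls back to proband-only compatibility and the
    result carries the ``inferred`` flag.
    """
    ctx = chromosome_context
    proband = pedigree.proband_member
    pg = _genotype(genotypes, proband.sample_id)
    if pg is None:
        raise SegregationError(f"missing proband genotype for {proband.sample_id}")

    mother = pedigree.member(proband.mother) if proband.mother else None
    father = pedigree.member(proband.father) if proband.father else None
    mg = _genotype(genotypes, mother.sample_id) if mother else None
    fg = _genotype(genotypes, father.sample_id) if father else None

    flags: Set[str] = set()
    if (mother and mg is None) or (father and fg is None):
        flags.add("missing_parent_genotype")

    affected = [
        m for m in pedigree.affected_members() if _genotype(genotypes, m.sample_id)
    ]
    healthy = [
        (m, _genotype(genotypes, m.sample_id))
        for m in pedigree.unaffected_members()
        if _genotype(genotypes, m.sample_id) is not None
    ]

    def healthy_ok_dominant() -> bool:
        # under a dominant-acting pattern no healthy member may carry the alt
        return all(not g.carries_alt for _, g in healthy)

    def healthy_ok_recessive() -> bool:
        return all(
            not _is_recessive_genotype(g, m.sex, ctx) for m, g in healthy
        )

    def affected_share(predicate) -> bool:
        return all(predicate(m, genotypes.get(m.sample_id, GT.MISSING)) for m in affected)

    no_parental_data = (mother is None or mg is None) and (father is None or fg is None)
    if no_parental_data:
        return _proband_only(pg, proband, ctx, flags)

    het_like = pg == GT.HET or (
        pg == GT.HEMI and ctx in ("chrX", "chrY")
    )

    # --- Y-linked: male proband carries a chrY variant from the affected father
    if ctx == "chrY" and proband.sex == "male" and pg in (GT.HEMI, GT.HOM_ALT):
        if father is not None and fg is not None and fg.carries_alt:
            if (
                father.affected == "affected"
                and affected_share(lambda m, g: g.carries_alt or m.sex == "female")
                and all(not g.carries_alt for m, g in healthy if m.sex == "male")
            ):
                return SegregationResult("y_linked", ctx, frozenset(flags))
            return SegregationResult("unknown", ctx, frozenset(flags))

    # --- de novo: het proband, every available healthy parent hom-ref
    if het_like:
        parent_gts = [(mother, mg), (father, fg)]
        available = [(p, g) for p, g in parent_gts if p is not None and g is not None]
        if available and all(
            p.affected == "unaffected" and not g.carries_alt for p, g in available
        ):
            if affected_share(lambda m, g: g in (GT.HET, GT.HEMI)) and healthy_ok_dominant():
                return SegregationResult("de_novo", ctx, frozenset(flags))
            return SegregationResult("unknown", ctx, frozenset(flags))

    # --- X-linked recessive hemizygous male
    if ctx == "chrX" and proband.sex == "male" and pg in (GT.HEMI, GT.HOM_ALT):
        if mother is not None and mg == GT.HET and mother.affected == "unaffected":
            father_ok = fg is None or not fg.carries_alt
            if father_ok and healthy_ok_recessive() and affected_share(
                lambda m, g: _is_recessive_genotype(g, m.sex, ctx)
            ):
                return SegregationResult("x_linked_recessive_hemi", ctx, frozenset(flags))
            return SegregationResult("unknown", ctx, frozenset(flags))

    # --- recessive homozygous / isodisomy
    if _is_recessive_genotype(pg, proband.sex, ctx) and ctx != "chrY":
        if not affected_share(lambda m, g: _is_recessive_genotype(g, m.sex, ctx)):
            return SegregationResult("unknown", ctx, frozenset(flags))
        if not healthy_ok_recessive():
            return SegregationResult("unknown", ctx, frozenset(flags))

        def carrier(p: Optional[PedigreeMember], g: Optional[GT]) -> bool:
            if p is None or g is None:
                return False
            if ctx == "chrX" and p.sex == "male":
                return g in (GT.HEMI, GT.HOM_ALT)
            return g == GT.HET

        mother_healthy = mother is not None and mother.affected == "unaffected"
        father_healthy = father is not None and father.affected == "unaffected"
        m_carrier = mother_healthy and carrier(mother, mg)
        f_carrier = father_healthy and carrier(father, fg)
        m_ref = mg is not None and not mg.carries_alt
        f_ref = fg is not None and not fg.carries_alt

        if m_carrier and f_carrier:
            return SegregationResult("ar_homozygous", ctx, frozenset(flags))
        if ctx == "chrX" and proband.sex == "male" and m_carrier:
            # handled above, kept for completeness
            return SegregationResult("x_linked_recessive_hemi", ctx, frozenset(flags))
        if (m_carrier and f_ref) or (f_carrier and m_ref):
            if ctx == "chrX" and proband.sex == "female":
                return SegregationResult("isodisomy", ctx, frozenset(flags))
            if ctx == "autosomal":
                return SegregationResult("isodisomy", ctx, frozenset(flags))
        if (m_carrier and fg is None) or (f_carrier and mg is None):
            flags.add("isodisomy_indistinguishable")
            return SegregationResult("ar_homozygous", ctx, frozenset(flags))
        return SegregationResult("unknown", ctx, frozenset(flags))

    # --- dominant inherited: het proband with an affected carrier parent
    if het_like:
        for p, g in ((mother, mg), (father, fg)):
            if (
                p is not None
                and g is not None
                and p.affected == "affected"
                and g.carries_alt
            ):
                if affected_share(lambda m, g2: g2.carries_alt) and healthy_ok_dominant():
                    return SegregationResult("dominant_inherited", ctx, frozenset(flags))
                return SegregationResult("unknown", ctx, frozenset(flags))

    return SegregationResult("unknown", ctx, frozenset(flags))


def _proband_only(
    pg: GT, proband: PedigreeMember, ctx: str, flags: Set[str]
) -> SegregationResult:
    flags = set(flags) | {"inferred"}
    if _is_recessive_genotype(pg, proband.sex, ctx) and ctx != "chrY":
        if ctx == "chrX" and proband.sex == "male":
            return SegregationResult("x_linked_recessive_hemi", ctx, frozenset(flags))
        return SegregationResult("ar_homozygous", ctx, frozenset(flags))
    if pg == GT.HET:
        return SegregationResult("dominant_inherited", ctx, frozenset(flags))
    if ctx == "chrY" and pg in (GT.HEMI, GT.HOM_ALT) and proband.sex == "male":
        return SegregationResult("y_linked", ctx, frozenset(flags))
    return SegregationResult("unknown", ctx, frozenset(flags))


def parental_origin(record: VariantRecord, pedigree: Pedigree) -> str:
    """Phase a proband-het variant by pedigree.

    Returns maternal / paternal / de_novo / ambiguous (both parents carry) /
    unknown (parental genotypes unavailable).
    """
    proband = pedigree.proband_member
    mg = (
        _genotype(record.genotypes, proband.mother)
        if proband.mother
        else None
    )
    fg = (
        _genotype(record.genotypes, proband.father)
        if proband.father
        else None
    )
    if mg is None and fg is None:
        return "unknown"
    m_carries = mg is not None and mg.carries_alt
    f_carries = fg is not None and fg.carries_alt
    if m_carries and f_carries:
        return "ambiguous"
    if m_carries:
        return "maternal"
    if f_carries:
        return "paternal"
    if mg is not None and fg is not None:
        return "de_novo"
    return "unknown"


def detect_compound_het(
    variants: Sequence[VariantRecord], pedigree: Pedigree
) -> List[CompoundHetPair]:
    """Candidate trans pairs among a gene's proband-het variants.

    A pair qualifies when the pedigree-phased origins differ (one maternal,
    one paternal) or at least one variant is de novo; pairs with both
    variants from the same parent (cis) are excluded.  Without parental
    data every het pair is a candidate flagged ``unphased``; pairs involving
    an ambiguous origin are kept with the same flag.  A variant transmitted
    by an affected parent does not qualify.
    """
    proband_id = pedigree.proband
    proband = pedigree.proband_member
    hets = [
        v
        for v in variants
        if v.genotype(proband_id) == GT.HET
    ]
    genes = {v.gene for v in hets}
    if len(genes) > 1:
        raise ValueError(f"compound-het pairing requires a single gene, got {genes}")
    hets.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))

    def transmitting_parent_affected(origin: str) -> bool:
        if origin == "maternal" and proband.mother:
            return pedigree.member(proband.mother).affected == "affected"
        if origin == "paternal" and proband.father:
            return pedigree.member(proband.father).affected == "affected"
        return False

    pairs: List[CompoundHetPair] = []
    origins = {v.key: parental_origin(v, pedigree) for v in hets}
    for a, b in combinations(hets, 2):
        oa, ob = origins[a.key], origins[b.key]
        if transmitting_parent_affected(oa) or transmitting_parent_affected(ob):
            continue
        known = {oa, ob}
        if known <= {"maternal", "paternal", "de_novo"}:
            if oa == ob and oa != "de_novo":
                continue  # cis configuration
            pairs.append(CompoundHetPair(a, b, (oa, ob)))
        else:
            pairs.append(
                CompoundHetPair(a, b, (oa, ob), flags=frozenset({"unphased"}))
            )
    return pairs


# pattern -> MOI codes it supports, by chromosome context
_PATTERN_MOI = {
    ("de_novo", "autosomal"): {"AD"},
    ("de_novo", "chrX"): {"XLD"},
    ("dominant_inherited", "autosomal"): {"AD"},
    ("dominant_inherited", "chrX"): {"XLD"},
    ("ar_homozygous", "autosomal"): {"AR"},
    ("ar_homozygous", "chrX"): {"XLR"},
    ("ar_compound_het", "autosomal"): {"AR"},
    ("ar_compound_het", "chrX"): {"XLR"},
    ("isodisomy", "autosomal"): {"AR"},
    ("isodisomy", "chrX"): {"XLR"},
    ("x_linked_recessive_hemi", "chrX"): {"XLR"},
    ("y_linked", "chrY"): {"YL"},
}


def inheritance_match(
    result: SegregationResult, expected_moi: Optional[Set[str]]
) -> bool:
    """True iff the observed pattern maps into the gene's expected MOI set.

    Unknown patterns and genes absent from the MOI table never match.
    """
    if not expected_moi or result.pattern == "unknown":
        return False
    supported = _PATTERN_MOI.get((result.pattern, result.chromosome_context), set())
    return bool(supported & set(expected_moi))
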