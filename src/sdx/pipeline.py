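"""End-to-end case analysis: VCF/PED in, featured candidates out.

Wires the IO, filtering, similarity, pathogenicity and segregation modules
into the per-proband candidate table consumed by the rankers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

from .config import Settings, DEFAULT_SETTINGS
from .ontology import AnnotationSet, ICTable, OntologyGraph, phenotypic_score
from .pathogenicity import (
    AnnotationBundle,
    PathogenicityModel,
    acmg_class,
    default_model,
    pathogenicity_score,
    trigger_criteria,
)
from .ranker import CandidateDiagnosis, assemble_features, enumerate_candidates
from .variants import (
    Pedigree,
    VariantRecord,
    annotate_cohort_counts,
    filter_artifacts,
    filter_common,
    read_cohort_vcf,
    read_pedigree,
)

logger = logging.getLogger(__name__)

__all__ = ["CaseAnalysis", "analyze_case", "label_candidates", "bundle_from_record"]


@dataclass
class CaseAnalysis:
    pedigree: Pedigree
    records: List[VariantRecord]
    candidates: List[CandidateDiagnosis]
    phenotypic_by_gene: Dict[str, float]


def bundle_from_record(record: VariantRecord) -> AnnotationBundle:
    """Build the criteria annotation bundle from a record's INFO payload."""
    extra = record.extra_info
    dmg = extra.get("DMG")
    return AnnotationBundle(
        consequence=extra.get("CSQ"),
        population_af=record.population_af,
        damage_score=float(dmg) if dmg is not None else None,
        de_novo=extra.get("DNV") == "1",
        known_classification=extra.get("CLS"),
        gene_lof_mechanism=extra.get("LOF", "1") == "1",
    )


def analyze_case(
    vcf_source,
    ped_source,
    hpo_terms: Sequence[str],
    graph: OntologyGraph,
    annotations: AnnotationSet,
    ic: ICTable,
    settings: Settings = DEFAULT_SETTINGS,
    cohort_counts: Optional[Mapping[Tuple[str, int, str, str], int]] = None,
    model: Optional[PathogenicityModel] = None,
) -> CaseAnalysis:
    """Read, filter and feature-annotate one family's candidate diagnoses."""
    pedigree = read_pedigree(ped_source, proband_id=settings.proband_id)
    records = read_cohort_vcf(
        vcf_source,
        pedigree,
        af_key=settings.af_info_key,
        gene_key=settings.gene_info_key,
    )
    if cohort_counts is not None:
        records = annotate_cohort_counts(records, cohort_counts)
    records = filter_common(records, settings.af_threshold)
    records = filter_artifacts(records, settings.max_cohort_alleles)

    known_genes = set(annotations.gene_terms) | set(annotations.gene_diseases)
    candidates = enumerate_candidates(records, pedigree, known_genes)

    model = model or default_model()
    path_by_variant: Dict[Tuple[str, int, str, str], float] = {}
    class_by_variant: Dict[Tuple[str, int, str, str], str] = {}
    for r in records:
        if r.key in path_by_variant:
            continue
        profile = trigger_criteria(bundle_from_record(r), settings)
        path_by_variant[r.key] = pathogenicity_score(profile, model)
        class_by_variant[r.key] = acmg_class(profile)

    pheno_by_gene: Dict[str, float] = {}
    for gene in sorted({c.gene for c in candidates}):
        score = phenotypic_score(
            list(hpo_terms), gene, annotations, graph, ic,
            combination=settings.score_combination,
        )
        pheno_by_gene[gene] = score.combined

    featured = []
    for cand in candidates:
        moi = annotations.gene_moi.get(cand.gene)
        c = assemble_features(
            cand,
            phenotypic_similarity=pheno_by_gene[cand.gene],
            pathogenicity_by_variant=path_by_variant,
            pedigree=pedigree,
            expected_moi=moi,
            missing_is_pass=settings.missing_filter_is_pass,
        )
        worst = min(c.variants, key=lambda v: path_by_variant[v.key])
        featured.append(replace(c, acmg_class=class_by_variant[worst.key]))
    return CaseAnalysis(
        pedigree=pedigree,
        records=records,
        candidates=featured,
        phenotypic_by_gene=pheno_by_gene,
    )


def label_candidates(
    candidates: Sequence[CandidateDiagnosis],
    causative_variant_keys: FrozenSet[Tuple[str, int, str, str]],
) -> List[CandidateDiagnosis]:
    """Mark the candidate matching the truth keys causative, the rest not."""
    out = []
    found = False
    for c in candidates:
        keys = frozenset(v.key for v in c.variants)
        if keys == causative_variant_keys:
            out.append(replace(c, label="causative"))
            found = True
        else:
            out.append(replace(c, label="non_causative"))
    if not found:
        logger.warning("no candidate matches the causative truth keys")
    return out
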