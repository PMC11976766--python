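"""Self-contained synthetic fixtures: ontology, annotations and families.

Generates a mini phenotype ontology with gene/disease annotation corpora,
and per-family VCF/PED/HPO bundles in which one causative candidate is
planted under a requested inheritance pattern, with background variants
drawn Hardy-Weinberg-consistent within families.  Cohort-level artifact
alleles can be injected at controlled counts to exercise the preprocessing
filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .ontology import (
    AnnotationSet,
    ICTable,
    OntologyGraph,
    information_content,
    load_disease_annotations,
    load_gene_annotations,
    load_gene_diseases,
    load_ontology,
)

__all__ = [
    "SimulationConfig",
    "SyntheticResources",
    "SyntheticCase",
    "CohortSim",
    "make_mini_ontology",
    "simulate_case",
    "simulate_cohort",
]

PATTERNS_REQUIRING_PARENTS = {
    "de_novo",
    "ar_homozygous",
    "ar_compound_het",
    "isodisomy",
    "x_linked_recessive_hemi",
    "y_linked",
}

_AUTOSOMES = [f"chr{i}" for i in range(1, 23)]


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_probands: int = 10
    family_structure: str = "trio"          # proband_only | duo | trio | quartet
    variants_per_proband: int = 7700
    causative_moi: str = "de_novo"          # any supported inheritance pattern
    feature_separation: float = 1.0         # 0 = causative indistinguishable
    af_min: float = 1e-3
    af_max: float = 0.05
    fraction_common: float = 0.05           # background drawn above the AF filter
    fraction_pass_filter: float = 0.9
    n_true_terms: int = 4
    n_noise_terms: int = 2
    proband_sex: str = "male"
    artifact_allele_counts: Tuple[int, ...] = ()

    def __post_init__(self):
        if self.n_probands < 1 or self.variants_per_proband < 1:
            raise ValueError("counts must be positive")
        if not math.isfinite(self.feature_separation):
            raise ValueError("feature_separation must be finite")
        if self.family_structure not in ("proband_only", "duo", "trio", "quartet"):
            raise ValueError(f"unknown family structure {self.family_structure!r}")
        if (
            self.causative_moi in PATTERNS_REQUIRING_PARENTS
            and self.family_structure == "proband_only"
        ):
            raise ValueError(
                f"pattern {self.causative_moi} cannot be verified in a "
                "proband-only family"
            )


@dataclass
class SyntheticResources:
    graph: OntologyGraph
    annotations: AnnotationSet
    ic: ICTable
    obo_text: str
    gene2pheno_tsv: str
    disease2pheno_tsv: str
    gene2disease_tsv: str
    gene_chrom: Dict[str, str]
    genes: List[str]


@dataclass(frozen=True)
class TruthRecord:
    variant_keys: Tuple[Tuple[str, int, str, str], ...]
    gene: str
    pattern: str


@dataclass
class SyntheticCase:
    family_id: str
    vcf_text: str
    ped_text: str
    hpo_terms: List[str]
    truth: TruthRecord
    samples: List[str]


@dataclass
class CohortSim:
    config: SimulationConfig
    resources: SyntheticResources
    cases: List[SyntheticCase]
    cohort_allele_counts: Dict[Tuple[str, int, str, str], int]
    artifact_keys: List[Tuple[str, int, str, str]]


def _term_id(i: int) -> str:
    return f"HP:{i:07d}"


def make_mini_ontology(
    seed: int, n_terms: int = 200, n_genes: int = 50
) -> SyntheticResources:
    """Random rooted DAG plus coherent gene/disease annotations and MOI codes.

    Deterministic given the seed; the OBO/TSV texts round-trip through the
    package loaders, and the in-memory objects come from those loaders.
    """
    if n_terms < 10:
        raise ValueError("need at least 10 terms")
    rng = np.random.default_rng(seed)

    parents: Dict[int, List[int]] = {1: []}
    for i in range(2, n_terms + 1):
        k = 2 if (i > 4 and rng.random() < 0.2) else 1
        ps = rng.choice(np.arange(1, i), size=min(k, i - 1), replace=False)
        parents[i] = sorted(int(p) for p in ps)

    lines = ["format-version: 1.2", ""]
    for i in range(1, n_terms + 1):
        lines += [
            "[Term]",
            f"id: {_term_id(i)}",
            f"name: synthetic term {i}",
        ]
        lines += [f"is_a: {_term_id(p)} ! synthetic term {p}" for p in parents[i]]
        lines.append("")
    obo_text = "\n".join(lines)
    graph = load_ontology(obo_text)

    # genes annotated to coherent subtrees rooted at distinct anchor terms
    anchor_pool = [i for i in range(5, n_terms + 1)]
    rng.shuffle(anchor_pool)
    genes = [f"GENE{i:03d}" for i in range(1, n_genes + 1)]

    n_x = max(1, n_genes // 12)
    gene_chrom: Dict[str, str] = {}
    for i, gene in enumerate(genes):
        if i < n_x:
            gene_chrom[gene] = "chrX"
        elif i == n_x:
            gene_chrom[gene] = "chrY"
        else:
            gene_chrom[gene] = _AUTOSOMES[i % len(_AUTOSOMES)]

    g2p_rows: List[str] = []
    d2p_rows: List[str] = []
    g2d_rows: List[str] = []
    freq_tokens = ["", "HP:0040280", "HP:0040281", "HP:0040282", "45%", "3/4", "0.6"]
    for i, gene in enumerate(genes):
        anchor = anchor_pool[i % len(anchor_pool)]
        pool = sorted(graph.descendants(_term_id(anchor)))
        if len(pool) < 4:
            extra = sorted(graph.ancestors(_term_id(anchor)) - {graph.root})
            pool = sorted(set(pool) | set(extra))
        size = int(min(len(pool), rng.integers(3, 7)))
        chosen = sorted(
            rng.choice(pool, size=size, replace=False).tolist()
        ) if size < len(pool) else sorted(pool)
        disease = f"OMIM:6{i:05d}"
        moi = _gene_moi(gene_chrom[gene], rng)
        g2d_rows.append(f"{gene}\t{disease}\t{moi}")
        for t in chosen:
            g2p_rows.append(f"{gene}\t{t}")
            token = freq_tokens[int(rng.integers(0, len(freq_tokens)))]
            d2p_rows.append(f"{disease}\t{t}\t{token}")

    gene2pheno_tsv = "#gene_symbol\thpo_id\n" + "\n".join(g2p_rows) + "\n"
    disease2pheno_tsv = "#disease_id\thpo_id\tfrequency\n" + "\n".join(d2p_rows) + "\n"
    gene2disease_tsv = "#gene_symbol\tdisease_id\tmoi_code\n" + "\n".join(g2d_rows) + "\n"

    gene_terms = load_gene_annotations(gene2pheno_tsv, graph)
    disease_terms = load_disease_annotations(disease2pheno_tsv, graph)
    gene_diseases, gene_moi = load_gene_diseases(gene2disease_tsv)
    ann = AnnotationSet(
        gene_terms=gene_terms,
        disease_terms=disease_terms,
        gene_diseases=gene_diseases,
        gene_moi=gene_moi,
    )
    ann.validate(graph)
    ic = information_content(graph, ann)
    return SyntheticResources(
        graph=graph,
        annotations=ann,
        ic=ic,
        obo_text=obo_text,
        gene2pheno_tsv=gene2pheno_tsv,
        disease2pheno_tsv=disease2pheno_tsv,
        gene2disease_tsv=gene2disease_tsv,
        gene_chrom=gene_chrom,
        genes=genes,
    )


def _gene_moi(chrom: str, rng: np.random.Generator) -> str:
    if chrom == "chrX":
        return "XLR" if rng.random() < 0.7 else "XLD"
    if chrom == "chrY":
        return "YL"
    return "AR" if rng.random() < 0.5 else "AD"


_PATTERN_TO_MOI = {
    "de_novo": "AD",
    "dominant_inherited": "AD",
    "ar_homozygous": "AR",
    "ar_compound_het": "AR",
    "isodisomy": "AR",
    "x_linked_recessive_hemi": "XLR",
    "y_linked": "YL",
}


def _pick_causative_gene(
    resources: SyntheticResources, pattern: str, rng: np.random.Generator
) -> str:
    want_moi = _PATTERN_TO_MOI[pattern]
    want_ctx = (
        "chrX"
        if pattern == "x_linked_recessive_hemi"
        else "chrY"
        if pattern == "y_linked"
        else "autosomal"
    )
    pool = [
        g
        for g in resources.genes
        if want_moi in resources.annotations.gene_moi.get(g, set())
        and (
            (want_ctx == "autosomal" and resources.gene_chrom[g] not in ("chrX", "chrY"))
            or resources.gene_chrom[g] == want_ctx
        )
    ]
    if not pool:
        raise ValueError(f"no gene compatible with pattern {pattern}")
    return pool[int(rng.integers(0, len(pool)))]


@dataclass
class _Row:
    chrom: str
    pos: int
    ref: str
    alt: str
    info: Dict[str, str]
    filter_field: str
    gts: Dict[str, str]      # sample -> VCF GT string


_BASES = "ACGT"


def _snv(rng: np.random.Generator) -> Tuple[str, str]:
    ref = _BASES[int(rng.integers(0, 4))]
    alt = _BASES[int(rng.integers(0, 4))]
    while alt == ref:
        alt = _BASES[int(rng.integers(0, 4))]
    return ref, alt


def _hw_diploid(af: float, rng: np.random.Generator) -> Tuple[int, int]:
    return (
        int(rng.random() < af),
        int(rng.random() < af),
    )


def _gt(a: int, b: int) -> str:
    return f"{min(a, b)}/{max(a, b)}"


def _family_samples(family_id: str, structure: str) -> Dict[str, str]:
    roles = {"proband": f"{family_id}_P"}
    if structure in ("duo", "trio", "quartet"):
        roles["mother"] = f"{family_id}_M"
    if structure in ("trio", "quartet"):
        roles["father"] = f"{family_id}_F"
    if structure == "quartet":
        roles["sibling"] = f"{family_id}_S"
    return roles


def simulate_case(
    config: SimulationConfig,
    resources: SyntheticResources,
    case_index: int,
) -> SyntheticCase:
    """One family bundle with a planted causative under the requested pattern."""
    rng = np.random.default_rng([config.seed, 9176, case_index])
    family_id = f"FAM{case_index:03d}"
    roles = _family_samples(family_id, config.family_structure)
    samples = list(roles.values())
    sep = max(0.0, min(1.0, config.feature_separation))

    causative_gene = _pick_causative_gene(resources, config.causative_moi, rng)
    rows: List[_Row] = []
    pos_base = 1_000_000 * (case_index + 1)

    background_genes = [
        g
        for g in resources.genes
        if resources.gene_chrom[g] != "chrY"
    ]
    for i in range(config.variants_per_proband):
        gene = background_genes[i % len(background_genes)]
        chrom = resources.gene_chrom[gene]
        ref, alt = _snv(rng)
        if rng.random() < config.fraction_common:
            af = float(rng.uniform(config.af_max + 1e-4, 0.5))
        else:
            af = float(rng.uniform(config.af_min, config.af_max))
        gts = _background_genotypes(chrom, af, roles, config.proband_sex, rng)
        filt = "PASS" if rng.random() < config.fraction_pass_filter else "LowQual"
        dmg = float(np.clip(rng.beta(2, 8), 0.0, 1.0))
        csq = "missense_variant" if rng.random() < 0.6 else "synonymous_variant"
        rows.append(
            _Row(
                chrom=chrom,
                pos=pos_base + 50 * (i + 1),
                ref=ref,
                alt=alt,
                info={
                    "AF": f"{af:.6f}",
                    "GENE": gene,
                    "DMG": f"{dmg:.4f}",
                    "CSQ": csq,
                    "DNV": "0",
                },
                filter_field=filt,
                gts=gts,
            )
        )

    truth_rows = _plant_causative(
        config, resources, causative_gene, roles, pos_base, rng, sep
    )
    rows.extend(truth_rows)
    truth = TruthRecord(
        variant_keys=tuple((r.chrom, r.pos, r.ref, r.alt) for r in truth_rows),
        gene=causative_gene,
        pattern=config.causative_moi,
    )

    hpo_terms = _sample_phenotype(config, resources, causative_gene, rng, sep)
    ped_text = _render_ped(family_id, roles, config)
    vcf_text = _render_vcf(rows, samples)
    return SyntheticCase(
        family_id=family_id,
        vcf_text=vcf_text,
        ped_text=ped_text,
        hpo_terms=hpo_terms,
        truth=truth,
        samples=samples,
    )


def _background_genotypes(
    chrom: str,
    af: float,
    roles: Dict[str, str],
    proband_sex: str,
    rng: np.random.Generator,
) -> Dict[str, str]:
    """Hardy-Weinberg parental draws with Mendelian transmission."""
    out: Dict[str, str] = {}
    on_x = chrom == "chrX"
    ma, mb = _hw_diploid(af, rng) if "mother" in roles else (0, 0)
    if on_x:
        fa = int(rng.random() < af) if "father" in roles else 0
        fb = fa
    else:
        fa, fb = _hw_diploid(af, rng) if "father" in roles else (0, 0)

    def child_gt(sex: str) -> str:
        m_allele = ma if rng.random() < 0.5 else mb
        if on_x and sex == "male":
            return str(m_allele)
        f_allele = fa if rng.random() < 0.5 else fb
        return _gt(m_allele, f_allele)

    if "mother" in roles:
        out[roles["mother"]] = _gt(ma, mb)
    if "father" in roles:
        out[roles["father"]] = str(fa) if on_x else _gt(fa, fb)
    out[roles["proband"]] = child_gt(proband_sex)
    if "sibling" in roles:
        out[roles["sibling"]] = child_gt("female")
    return out


def _plant_causative(
    config: SimulationConfig,
    resources: SyntheticResources,
    gene: str,
    roles: Dict[str, str],
    pos_base: int,
    rng: np.random.Generator,
    sep: float,
) -> List[_Row]:
    chrom = resources.gene_chrom[gene]
    pattern = config.causative_moi
    proband = roles["proband"]
    mother = roles.get("mother")
    father = roles.get("father")
    sibling = roles.get("sibling")

    def make_row(offset: int, gts: Dict[str, str], dnv: bool) -> _Row:
        ref, alt = _snv(rng)
        # interpolate annotation strength: at sep=0 the causative looks like
        # background (damage law, AF present, unconfirmed de novo)
        bg_dmg = float(np.clip(rng.beta(2, 8), 0.0, 1.0))
        dmg = bg_dmg + sep * (0.97 - bg_dmg)
        info = {
            "GENE": gene,
            "DMG": f"{min(dmg, 0.999):.4f}",
            "CSQ": "stop_gained" if sep >= 0.5 else "missense_variant",
            "DNV": "1" if (dnv and sep > 0) else "0",
            "LOF": "1",
        }
        if sep < 0.5:
            info["AF"] = f"{rng.uniform(config.af_min, config.af_max):.6f}"
        if sibling and sibling not in gts:
            gts[sibling] = "0" if chrom in ("chrY",) else "0/0"
        return _Row(
            chrom=chrom,
            pos=pos_base + 999_000 + offset,
            ref=ref,
            alt=alt,
            info=info,
            filter_field="PASS",
            gts=gts,
        )

    if pattern == "de_novo":
        gts = {proband: "0/1"}
        if mother:
            gts[mother] = "0/0"
        if father:
            gts[father] = "0/0"
        return [make_row(0, gts, dnv=True)]
    if pattern == "ar_homozygous":
        gts = {proband: "1/1"}
        if mother:
            gts[mother] = "0/1"
        if father:
            gts[father] = "0/1"
        return [make_row(0, gts, dnv=False)]
    if pattern == "isodisomy":
        gts = {proband: "1/1"}
        if mother:
            gts[mother] = "0/1"
        if father:
            gts[father] = "0/0"
        return [make_row(0, gts, dnv=False)]
    if pattern == "ar_compound_het":
        g1 = {proband: "0/1"}
        g2 = {proband: "0/1"}
        if mother:
            g1[mother], g2[mother] = "0/1", "0/0"
        if father:
            g1[father], g2[father] = "0/0", "0/1"
        return [make_row(0, g1, dnv=False), make_row(50, g2, dnv=False)]
    if pattern == "x_linked_recessive_hemi":
        if config.proband_sex != "male":
            raise ValueError("x_linked_recessive_hemi needs a male proband")
        gts = {proband: "1"}
        if mother:
            gts[mother] = "0/1"
        if father:
            gts[father] = "0"
        return [make_row(0, gts, dnv=False)]
    if pattern == "y_linked":
        if config.proband_sex != "male":
            raise ValueError("y_linked needs a male proband")
        gts = {proband: "1"}
        if father:
            gts[father] = "1"
        if mother:
            gts[mother] = "."
        return [make_row(0, gts, dnv=False)]
    if pattern == "dominant_inherited":
        gts = {proband: "0/1"}
        if mother:
            gts[mother] = "0/1"  # affected carrier mother (see PED)
        if father:
            gts[father] = "0/0"
        return [make_row(0, gts, dnv=False)]
    raise ValueError(f"unknown causative pattern {pattern!r}")


def _sample_phenotype(
    config: SimulationConfig,
    resources: SyntheticResources,
    gene: str,
    rng: np.random.Generator,
    sep: float,
) -> List[str]:
    diseases = sorted(resources.annotations.gene_diseases.get(gene, set()))
    weighted = resources.annotations.disease_terms.get(diseases[0], {}) if diseases else {}
    terms = sorted(weighted)
    k = max(1, int(round(config.n_true_terms * sep)))
    chosen: List[str] = []
    if terms and sep > 0:
        w = np.array([1.0 if weighted[t] is None else weighted[t] for t in terms])
        w = w / w.sum()
        k = min(k, len(terms))
        chosen = sorted(
            rng.choice(terms, size=k, replace=False, p=w).tolist()
        )
    all_terms = sorted(resources.graph.terms - {resources.graph.root})
    n_noise = config.n_noise_terms + (config.n_true_terms if sep == 0 else 0)
    noise = rng.choice(all_terms, size=min(n_noise, len(all_terms)), replace=False)
    out = sorted(set(chosen) | set(str(t) for t in noise))
    return out


def _render_ped(family_id: str, roles: Dict[str, str], config: SimulationConfig) -> str:
    sex_code = {"male": "1", "female": "2"}
    p_sex = sex_code.get(config.proband_sex, "0")
    mother = roles.get("mother", "0")
    father = roles.get("father", "0")
    father_affected = config.causative_moi == "y_linked"
    mother_affected = config.causative_moi == "dominant_inherited"
    lines = []
    if "father" in roles:
        lines.append(
            f"{family_id}\t{father}\t0\t0\t1\t{'2' if father_affected else '1'}"
        )
    if "mother" in roles:
        lines.append(
            f"{family_id}\t{mother}\t0\t0\t2\t{'2' if mother_affected else '1'}"
        )
    lines.append(
        f"{family_id}\t{roles['proband']}\t{father if 'father' in roles else '0'}"
        f"\t{mother if 'mother' in roles else '0'}\t{p_sex}\t2"
    )
    if "sibling" in roles:
        lines.append(f"{family_id}\t{roles['sibling']}\t{father}\t{mother}\t2\t1")
    return "\n".join(lines) + "\n"


_VCF_INFO_HEADER = [
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Population allele frequency">',
    '##INFO=<ID=GENE,Number=A,Type=String,Description="Gene symbol">',
    '##INFO=<ID=DMG,Number=A,Type=Float,Description="In-silico damage score">',
    '##INFO=<ID=CSQ,Number=A,Type=String,Description="Consequence">',
    '##INFO=<ID=DNV,Number=A,Type=Integer,Description="Confirmed de novo">',
    '##INFO=<ID=LOF,Number=A,Type=Integer,Description="Gene has LOF mechanism">',
    '##INFO=<ID=CLS,Number=A,Type=String,Description="Known classification">',
    '##FILTER=<ID=LowQual,Description="Low quality">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def _render_vcf(rows: Sequence[_Row], samples: Sequence[str]) -> str:
    chroms = []
    for r in rows:
        if r.chrom not in chroms:
            chroms.append(r.chrom)
    header = ["##fileformat=VCFv4.2"]
    header += [f"##contig=<ID={c}>" for c in sorted(chroms)]
    header += _VCF_INFO_HEADER
    header.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    body = []
    for r in sorted(rows, key=lambda r: (r.chrom, r.pos)):
        info = ";".join(f"{k}={v}" for k, v in r.info.items())
        gts = "\t".join(r.gts.get(s, "./.") for s in samples)
        body.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t{r.filter_field}\t{info}\tGT\t{gts}"
        )
    return "\n".join(header + body) + "\n"


def simulate_cohort(config: SimulationConfig) -> CohortSim:
    """Families plus optional shared artifact variants at fixed allele counts."""
    resources = make_mini_ontology(config.seed, n_terms=200, n_genes=50)
    cases = [simulate_case(config, resources, i) for i in range(config.n_probands)]

    artifact_keys: List[Tuple[str, int, str, str]] = []
    for j, target in enumerate(config.artifact_allele_counts):
        key, per_family = _artifact_plan(config, resources, j, target)
        artifact_keys.append(key)
        for case, n_alleles in zip(cases, per_family):
            if n_alleles == 0:
                continue
            case.vcf_text = _inject_artifact(case, key, n_alleles)

    counts = _true_allele_counts(cases)
    return CohortSim(
        config=config,
        resources=resources,
        cases=cases,
        cohort_allele_counts=counts,
        artifact_keys=artifact_keys,
    )


def _artifact_plan(
    config: SimulationConfig,
    resources: SyntheticResources,
    index: int,
    target: int,
) -> Tuple[Tuple[str, int, str, str], List[int]]:
    gene = next(
        g for g in resources.genes if resources.gene_chrom[g] not in ("chrX", "chrY")
    )
    chrom = resources.gene_chrom[gene]
    key = (chrom, 999_000_000 + index * 10, "A", "G")
    capacity = {"proband_only": 2, "duo": 4, "trio": 6, "quartet": 8}[
        config.family_structure
    ]
    per_family = []
    remaining = target
    for _ in range(config.n_probands):
        take = min(remaining, capacity)
        per_family.append(take)
        remaining -= take
    if remaining > 0:
        raise ValueError(
            f"cohort too small to host {target} artifact alleles"
        )
    return key, per_family


def _inject_artifact(
    case: SyntheticCase, key: Tuple[str, int, str, str], n_alleles: int
) -> str:
    chrom, pos, ref, alt = key
    gts = []
    remaining = n_alleles
    for _ in case.samples:
        take = min(remaining, 2)
        gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[take])
        remaining -= take
    gene = "ARTIFACT"
    line = (
        f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t"
        f"GENE={gene};DMG=0.1000;CSQ=missense_variant;DNV=0\tGT\t" + "\t".join(gts)
    )
    text = case.vcf_text.rstrip("\n").split("\n")
    # keep header contig list consistent: artifact lives on an existing contig
    text.append(line)
    header = [l for l in text if l.startswith("#")]
    body = sorted(
        (l for l in text if not l.startswith("#")),
        key=lambda l: (l.split("\t")[0], int(l.split("\t")[1])),
    )
    return "\n".join(header + body) + "\n"


def _true_allele_counts(
    cases: Sequence[SyntheticCase],
) -> Dict[Tuple[str, int, str, str], int]:
    counts: Dict[Tuple[str, int, str, str], int] = {}
    for case in cases:
        for line in case.vcf_text.splitlines():
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            key = (cols[0], int(cols[1]), cols[3], cols[4])
            n = 0
            for gt in cols[9:]:
                n += sum(1 for a in gt.replace("|", "/").split("/") if a == "1")
            counts[key] = counts.get(key, 0) + n
    return counts
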