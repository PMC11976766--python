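"""Multi-sample VCF and pedigree IO plus cohort-level preprocessing filters.

Sites are decomposed so every record carries exactly one alt allele; indels
are trimmed (shared suffix then prefix) before decomposition.  Filtering
removes common variants (population AF strictly above a threshold) and
cohort-wide sequencing artifacts (alt-allele count strictly above a
threshold), in either order.
"""

from __future__ import annotations

import enum
import logging
import os
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = [
    "GT",
    "VariantRecord",
    "PedigreeMember",
    "Pedigree",
    "PedigreeError",
    "VcfError",
    "read_cohort_vcf",
    "read_pedigree",
    "filter_common",
    "filter_artifacts",
    "count_cohort_alleles",
    "annotate_cohort_counts",
    "chromosome_context",
]


class GT(enum.Enum):
    HOM_REF = "hom-ref"
    HET = "het"
    HOM_ALT = "hom-alt"
    HEMI = "hemizygous"
    MISSING = "missing"

    @property
    def alt_alleles(self) -> int:
        return {GT.HOM_REF: 0, GT.HET: 1, GT.HOM_ALT: 2, GT.HEMI: 1, GT.MISSING: 0}[self]

    @property
    def carries_alt(self) -> bool:
        return self in (GT.HET, GT.HOM_ALT, GT.HEMI)


class VcfError(ValueError):
    pass


class PedigreeError(ValueError):
    pass


def chromosome_context(chrom: str) -> str:
    """Classify a chromosome name as autosomal / chrX / chrY."""
    name = chrom.lower().removeprefix("chr")
    if name == "x":
        return "chrX"
    if name == "y":
        return "chrY"
    return "autosomal"


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int                       # 1-based, after trimming
    ref: str
    alt: str
    gene: Optional[str] = None
    population_af: Optional[float] = None
    filter_field: str = "."
    genotypes: Mapping[str, GT] = field(default_factory=dict)
    cohort_alt_allele_count: int = 0
    extra_info: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise VcfError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise VcfError("ref/alt alleles must be non-empty")
        if self.ref == self.alt:
            raise VcfError(f"alt equals ref at {self.chrom}:{self.pos}")

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def context(self) -> str:
        return chromosome_context(self.chrom)

    def genotype(self, sample: str) -> GT:
        return self.genotypes.get(sample, GT.MISSING)


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    sex: str                  # "male" | "female" | "unknown"
    affected: str             # "affected" | "unaffected" | "unknown"
    mother: Optional[str] = None
    father: Optional[str] = None


@dataclass(frozen=True)
class Pedigree:
    members: Tuple[PedigreeMember, ...]
    proband: str

    def __post_init__(self):
        ids = {m.sample_id for m in self.members}
        by_id = {m.sample_id: m for m in self.members}
        if self.proband not in ids:
            raise PedigreeError(f"proband {self.proband} not among members")
        if by_id[self.proband].affected != "affected":
            raise PedigreeError(f"proband {self.proband} is not affected")
        for m in self.members:
            for parent in (m.mother, m.father):
                if parent is not None and parent not in ids:
                    raise PedigreeError(f"{m.sample_id}: unresolved parent {parent}")
        # no individual may be its own ancestor
        for m in self.members:
            seen = set()
            frontier = [p for p in (m.mother, m.father) if p]
            while frontier:
                cur = frontier.pop()
                if cur == m.sample_id:
                    raise PedigreeError(f"{m.sample_id} is its own ancestor")
                if cur in seen:
                    continue
                seen.add(cur)
                parent = by_id[cur]
                frontier.extend(p for p in (parent.mother, parent.father) if p)

    def member(self, sample_id: str) -> PedigreeMember:
        for m in self.members:
            if m.sample_id == sample_id:
                return m
        raise PedigreeError(f"unknown member {sample_id}")

    @property
    def proband_member(self) -> PedigreeMember:
        return self.member(self.proband)

    @property
    def sample_ids(self) -> List[str]:
        return [m.sample_id for m in self.members]

    def affected_members(self) -> List[PedigreeMember]:
        return [m for m in self.members if m.affected == "affected"]

    def unaffected_members(self) -> List[PedigreeMember]:
        return [m for m in self.members if m.affected == "unaffected"]


_SEX_CODES = {"1": "male", "2": "female"}
_PHENO_CODES = {"1": "unaffected", "2": "affected"}


def read_pedigree(ped_stream, proband_id: Optional[str] = None) -> Pedigree:
    """Parse 6-column PED text (family, individual, father, mother, sex, phenotype).

    The proband defaults to the first affected individual in file order;
    ``proband_id`` overrides that choice.
    """
    if hasattr(ped_stream, "read"):
        text = ped_stream.read()
    else:
        text = ped_stream
    members: List[PedigreeMember] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 6:
            raise PedigreeError(f"PED line needs 6 columns: {line!r}")
        _fam, ind, father, mother, sex, pheno = cols[:6]
        members.append(
            PedigreeMember(
                sample_id=ind,
                sex=_SEX_CODES.get(sex, "unknown"),
                affected=_PHENO_CODES.get(pheno, "unknown"),
                mother=None if mother in ("0", ".", "") else mother,
                father=None if father in ("0", ".", "") else father,
            )
        )
    if not members:
        raise PedigreeError("empty pedigree")
    if proband_id is None:
        affected = [m for m in members if m.affected == "affected"]
        if not affected:
            raise PedigreeError("pedigree has no affected member")
        proband_id = affected[0].sample_id
    return Pedigree(members=tuple(members), proband=proband_id)


def _trim_allele(pos: int, ref: str, alt: str) -> Tuple[int, str, str]:
    """Trim shared suffix then shared prefix, keeping at least one base each."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _classify_alleles(
    alleles: Sequence[int], alt_index: int, hemi_ok: bool, where: str
) -> GT:
    called = [a for a in alleles if a >= 0]
    if not called:
        return GT.MISSING
    if len(called) < len(alleles):
        logger.warning("partially called genotype at %s treated as missing", where)
        return GT.MISSING
    n_alt = sum(1 for a in called if a == alt_index)
    if len(called) == 1:
        if hemi_ok:
            return GT.HEMI if n_alt == 1 else GT.HOM_REF
        return GT.HOM_ALT if n_alt == 1 else GT.HOM_REF
    if n_alt == 0:
        return GT.HOM_REF
    if n_alt == len(called):
        return GT.HOM_ALT
    return GT.HET


DEFAULT_INFO_KEYS = ("CSQ", "DMG", "DNV", "CLS")


def read_cohort_vcf(
    vcf_source,
    pedigree: Optional[Pedigree] = None,
    af_key: str = "AF",
    gene_key: str = "GENE",
    info_keys: Sequence[str] = DEFAULT_INFO_KEYS,
) -> List[VariantRecord]:
    """Read a VCF into decomposed, trimmed :class:`VariantRecord` objects.

    One record is produced per (site, alt allele).  Genotypes are mapped per
    sample; a single-allele call on chrX/chrY for a male (per the pedigree)
    is flagged hemizygous.  Population AF is taken from ``af_key`` in INFO,
    the gene symbol from ``gene_key``; any ``info_keys`` present are kept
    verbatim in ``extra_info`` for downstream annotation.
    """
    path, cleanup = _as_path(vcf_source)
    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        if not samples:
            raise VcfError("VCF has no sample columns / GT data")
        male = set()
        if pedigree is not None:
            male = {m.sample_id for m in pedigree.members if m.sex == "male"}
        records: List[VariantRecord] = []
        for v in vcf:
            alts = v.ALT or []
            ctx = chromosome_context(v.CHROM)
            af_raw = v.INFO.get(af_key)
            gene_raw = v.INFO.get(gene_key)
            # htslib reports PASS as ['PASS'] and a missing FILTER as []
            filts = v.FILTERS
            raw_filter_col = ";".join(filts) if filts else "."
            for k, alt in enumerate(alts, start=1):
                if alt in (".", "*", ""):
                    continue
                af = _per_alt(af_raw, k - 1)
                gene = _per_alt(gene_raw, k - 1)
                extra = {}
                for key in info_keys:
                    val = _per_alt(v.INFO.get(key), k - 1)
                    if val is not None:
                        extra[key] = str(val)
                gts: Dict[str, GT] = {}
                for si, sample in enumerate(samples):
                    alleles = [int(a) for a in v.genotypes[si][:-1]]
                    hemi_ok = ctx in ("chrX", "chrY") and sample in male
                    gts[sample] = _classify_alleles(
                        alleles, k, hemi_ok, f"{v.CHROM}:{v.POS}/{sample}"
                    )
                pos, ref, a = _trim_allele(v.POS, v.REF, alt)
                records.append(
                    VariantRecord(
                        chrom=v.CHROM,
                        pos=pos,
                        ref=ref,
                        alt=a,
                        gene=str(gene) if gene is not None else None,
                        population_af=_f32_clean(af) if af is not None else None,
                        filter_field=raw_filter_col,
                        genotypes=gts,
                        extra_info=extra,
                    )
                )
        return records
    finally:
        if cleanup:
            os.unlink(path)


def _f32_clean(value: float) -> float:
    """Undo float32 widening noise (htslib stores INFO floats as float32)."""
    import numpy as np

    return float(np.format_float_positional(np.float32(value)))


def _per_alt(value, index: int):
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        return value[index] if index < len(value) else None
    if isinstance(value, str) and "," in value:
        parts = value.split(",")
        return parts[index] if index < len(parts) else None
    return value


def _as_path(source) -> Tuple[Path, bool]:
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        return Path(source), False
    text = source.read() if hasattr(source, "read") else str(source)
    fd, name = tempfile.mkstemp(suffix=".vcf")
    with os.fdopen(fd, "w") as fh:
        fh.write(text)
    return Path(name), True


def filter_common(
    records: Iterable[VariantRecord], af_threshold: float = 0.05
) -> List[VariantRecord]:
    """Drop records whose population AF is strictly above the threshold.

    Records without a population AF are retained.
    """
    if not 0.0 <= af_threshold <= 1.0:
        raise ValueError(f"af_threshold must be in [0,1], got {af_threshold}")
    return [
        r
        for r in records
        if r.population_af is None or r.population_af <= af_threshold
    ]


def filter_artifacts(
    records: Iterable[VariantRecord], max_cohort_alleles: int = 13
) -> List[VariantRecord]:
    """Drop records seen in strictly more cohort alt alleles than allowed."""
    return [r for r in records if r.cohort_alt_allele_count <= max_cohort_alleles]


def count_cohort_alleles(
    family_records: Sequence[Sequence[VariantRecord]],
) -> Dict[Tuple[str, int, str, str], int]:
    """Total alt-allele counts per variant across every sample of every family.

    Hom-alt contributes 2 alleles, het and hemizygous 1 each.
    """
    counts: Dict[Tuple[str, int, str, str], int] = {}
    for records in family_records:
        for r in records:
            n = sum(g.alt_alleles for g in r.genotypes.values())
            counts[r.key] = counts.get(r.key, 0) + n
    return counts


def annotate_cohort_counts(
    records: Iterable[VariantRecord],
    counts: Mapping[Tuple[str, int, str, str], int],
) -> List[VariantRecord]:
    return [
        replace(r, cohort_alt_allele_count=counts.get(r.key, 0)) for r in records
    ]
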