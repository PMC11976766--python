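"""Phenotype ontology handling and semantic similarity.

Parses an OBO-format ontology into an is-a DAG, loads gene/disease
phenotype-annotation corpora, computes disease-corpus information content,
Resnik pairwise similarity, the best-match-average (BMA) set similarity
with optional per-term frequency weights, and the combined gene/condition
phenotypic score used as a ranking feature.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx

__all__ = [
    "OntologyGraph",
    "AnnotationSet",
    "ICTable",
    "PhenotypicScore",
    "OntologyError",
    "load_ontology",
    "load_gene_annotations",
    "load_disease_annotations",
    "load_gene_diseases",
    "information_content",
    "resnik",
    "bma_similarity",
    "phenotypic_score",
    "rank_genes_by_phenotype",
    "parse_frequency",
]


class OntologyError(ValueError):
    """Raised for structural problems in the ontology or its annotations."""


# Midpoints of the frequency-modifier ranges defined by the phenotype
# ontology's frequency subontology (obligate, very frequent, frequent,
# occasional, very rare).  "excluded" (0%) carries no positive weight and is
# treated as an absent annotation by the loaders.
FREQUENCY_MODIFIER_MIDPOINTS: Dict[str, float] = {
    "HP:0040280": 1.0,     # obligate, 100%
    "HP:0040281": 0.895,   # very frequent, 80-99%
    "HP:0040282": 0.545,   # frequent, 30-79%
    "HP:0040283": 0.17,    # occasional, 5-29%
    "HP:0040284": 0.025,   # very rare, 1-4%
}
FREQUENCY_EXCLUDED = "HP:0040285"


@dataclass(frozen=True)
class OntologyGraph:
    """Is-a DAG over phenotype terms.

    ``parents`` maps each term to its direct is-a parents; the root has no
    parents.  Obsolete terms are kept out of ``terms`` and are reachable
    only through ``obsolete_map``.
    """

    terms: FrozenSet[str]
    parents: Mapping[str, FrozenSet[str]]
    root: str
    obsolete_map: Mapping[str, str] = field(default_factory=dict)
    _ancestor_cache: Dict[str, FrozenSet[str]] = field(
        default_factory=dict, repr=False, compare=False, hash=False
    )
    _descendant_cache: Dict[str, FrozenSet[str]] = field(
        default_factory=dict, repr=False, compare=False, hash=False
    )

    def resolve(self, term: str) -> str:
        """Map an obsolete term to its replacement; identity otherwise."""
        seen = set()
        while term in self.obsolete_map:
            if term in seen:
                raise OntologyError(f"cyclic replaced_by chain at {term}")
            seen.add(term)
            term = self.obsolete_map[term]
        return term

    def ancestors(self, term: str) -> FrozenSet[str]:
        """All terms reachable by is-a edges, including ``term`` itself."""
        term = self.resolve(term)
        if term not in self.terms:
            raise OntologyError(f"unknown term: {term}")
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out: Set[str] = {term}
        stack = [term]
        while stack:
            for p in self.parents.get(stack.pop(), ()):
                if p not in out:
                    out.add(p)
                    stack.append(p)
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def descendants(self, term: str) -> FrozenSet[str]:
        """All terms that have ``term`` as an ancestor, including itself."""
        if not self._descendant_cache:
            children: Dict[str, Set[str]] = {t: set() for t in self.terms}
            for child, ps in self.parents.items():
                for p in ps:
                    children[p].add(child)
            order = list(nx.topological_sort(self._digraph()))
            # topological order points child -> parent, so children come first
            desc: Dict[str, Set[str]] = {t: {t} for t in self.terms}
            for t in order:
                for c in children[t]:
                    desc[t] |= desc[c]
            for t, s in desc.items():
                self._descendant_cache[t] = frozenset(s)
        term = self.resolve(term)
        if term not in self.terms:
            raise OntologyError(f"unknown term: {term}")
        return self._descendant_cache[term]

    def _digraph(self) -> "nx.DiGraph":
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            for p in ps:
                g.add_edge(child, p)
        return g


@dataclass
class AnnotationSet:
    """Phenotype annotation corpora for genes and diseases.

    ``disease_terms`` maps each disease to ``{term: weight-or-None}`` where a
    weight, when present, is the term's frequency in the disease in (0, 1].
    """

    gene_terms: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    disease_terms: Dict[str, Dict[str, Optional[float]]] = field(default_factory=dict)
    gene_diseases: Dict[str, Set[str]] = field(default_factory=dict)
    gene_moi: Dict[str, Set[str]] = field(default_factory=dict)

    def validate(self, graph: OntologyGraph) -> None:
        for gene, terms in self.gene_terms.items():
            for t in terms:
                if graph.resolve(t) not in graph.terms:
                    raise OntologyError(f"gene {gene} annotated to unknown term {t}")
        for disease, weighted in self.disease_terms.items():
            for t, w in weighted.items():
                if graph.resolve(t) not in graph.terms:
                    raise OntologyError(f"disease {disease} annotated to unknown term {t}")
                if w is not None and not (0.0 < w <= 1.0):
                    raise OntologyError(
                        f"frequency weight {w} for {disease}/{t} outside (0, 1]"
                    )


@dataclass(frozen=True)
class ICTable:
    """Per-term information content in nats."""

    ic: Mapping[str, float]

    def __getitem__(self, term: str) -> float:
        return self.ic[term]


@dataclass(frozen=True)
class PhenotypicScore:
    gene_score: float
    condition_score: float
    combined: float
    no_annotation: bool = False


_STANZA_RE = re.compile(r"^\[(?P<name>[^\]]+)\]\s*$")


def load_ontology(obo_stream) -> OntologyGraph:
    """Parse OBO text into an :class:`OntologyGraph`.

    Only ``is_a`` relationships become edges.  Obsolete terms are excluded
    from the term set and recorded in ``obsolete_map`` when they carry a
    ``replaced_by`` tag.
    """
    if isinstance(obo_stream, (str, bytes)):
        obo_stream = io.StringIO(
            obo_stream.decode() if isinstance(obo_stream, bytes) else obo_stream
        )

    terms: Set[str] = set()
    parents: Dict[str, Set[str]] = {}
    obsolete_map: Dict[str, str] = {}

    cur_id: Optional[str] = None
    cur_parents: Set[str] = set()
    cur_obsolete = False
    cur_replacement: Optional[str] = None
    in_term_stanza = False

    def flush() -> None:
        nonlocal cur_id, cur_parents, cur_obsolete, cur_replacement
        if cur_id is not None:
            if cur_obsolete:
                if cur_replacement is not None:
                    obsolete_map[cur_id] = cur_replacement
            else:
                terms.add(cur_id)
                parents[cur_id] = set(cur_parents)
        cur_id, cur_parents, cur_obsolete, cur_replacement = None, set(), False, None

    for raw in obo_stream:
        line = raw.split("!", 1)[0].strip()
        m = _STANZA_RE.match(line)
        if m:
            flush()
            in_term_stanza = m.group("name") == "Term"
            continue
        if not in_term_stanza or not line or ":" not in line:
            continue
        tag, _, value = line.partition(":")
        tag, value = tag.strip(), value.strip()
        if tag == "id":
            cur_id = value
        elif tag == "is_a":
            cur_parents.add(value.split()[0])
        elif tag == "is_obsolete" and value.lower() == "true":
            cur_obsolete = True
        elif tag == "replaced_by":
            cur_replacement = value.split()[0]

    flush()

    for child, ps in parents.items():
        for p in ps:
            if p not in terms:
                raise OntologyError(f"term {child} references unknown parent {p}")

    roots = [t for t in terms if not parents[t]]
    if len(roots) != 1:
        raise OntologyError(f"expected exactly one root term, found {sorted(roots)}")

    g = nx.DiGraph()
    g.add_nodes_from(terms)
    for child, ps in parents.items():
        for p in ps:
            g.add_edge(child, p)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        u, v = cycle[0][0], cycle[0][1]
        raise OntologyError(f"ontology contains a cycle through edge {u} -> {v}")

    return OntologyGraph(
        terms=frozenset(terms),
        parents={t: frozenset(ps) for t, ps in parents.items()},
        root=roots[0],
        obsolete_map=dict(obsolete_map),
    )


def parse_frequency(token: str) -> Optional[float]:
    """Parse a disease-annotation frequency field into a weight in (0, 1].

    Accepts an empty field (-> None), a fraction ``k/n``, a percentage
    ``12%``/``12.5%``, or a frequency-modifier term ID.  The "excluded"
    modifier and zero frequencies return None (no positive contribution).
    """
    token = token.strip()
    if not token or token == ".":
        return None
    if token == FREQUENCY_EXCLUDED:
        return None
    if token in FREQUENCY_MODIFIER_MIDPOINTS:
        return FREQUENCY_MODIFIER_MIDPOINTS[token]
    if token.endswith("%"):
        value = float(token[:-1]) / 100.0
    elif "/" in token:
        num, den = token.split("/", 1)
        den_f = float(den)
        if den_f == 0:
            raise OntologyError(f"zero denominator in frequency {token!r}")
        value = float(num) / den_f
    else:
        value = float(token)
    if value <= 0.0:
        return None
    if value > 1.0:
        raise OntologyError(f"frequency {token!r} above 1")
    return value


def _tsv_rows(stream) -> Iterable[List[str]]:
    if isinstance(stream, (str, bytes)):
        stream = io.StringIO(stream.decode() if isinstance(stream, bytes) else stream)
    for raw in stream:
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        yield line.split("\t")


def load_gene_annotations(stream, graph: Optional[OntologyGraph] = None) -> Dict[str, FrozenSet[str]]:
    """Load a (gene_symbol, hpo_id) TSV into a gene -> term-set map."""
    out: Dict[str, Set[str]] = {}
    for row in _tsv_rows(stream):
        if len(row) < 2:
            raise OntologyError(f"gene annotation row needs 2 columns: {row!r}")
        gene, term = row[0].strip(), row[1].strip()
        if graph is not None:
            term = graph.resolve(term)
        out.setdefault(gene, set()).add(term)
    return {g: frozenset(ts) for g, ts in out.items()}


def load_disease_annotations(
    stream, graph: Optional[OntologyGraph] = None
) -> Dict[str, Dict[str, Optional[float]]]:
    """Load a (disease_id, hpo_id, frequency) TSV.

    The frequency column is optional and may be empty, ``k/n``, a
    percentage, or a frequency-modifier term ID.
    """
    out: Dict[str, Dict[str, Optional[float]]] = {}
    for row in _tsv_rows(stream):
        if len(row) < 2:
            raise OntologyError(f"disease annotation row needs >=2 columns: {row!r}")
        disease, term = row[0].strip(), row[1].strip()
        freq = parse_frequency(row[2]) if len(row) > 2 else None
        if graph is not None:
            term = graph.resolve(term)
        out.setdefault(disease, {})[term] = freq
    return out


def load_gene_diseases(stream) -> Tuple[Dict[str, Set[str]], Dict[str, Set[str]]]:
    """Load a (gene_symbol, disease_id, moi_code) TSV.

    Returns ``(gene -> diseases, gene -> MOI codes)``.
    """
    gene_diseases: Dict[str, Set[str]] = {}
    gene_moi: Dict[str, Set[str]] = {}
    for row in _tsv_rows(stream):
        if len(row) < 2:
            raise OntologyError(f"gene-disease row needs >=2 columns: {row!r}")
        gene, disease = row[0].strip(), row[1].strip()
        gene_diseases.setdefault(gene, set()).add(disease)
        if len(row) > 2 and row[2].strip():
            gene_moi.setdefault(gene, set()).add(row[2].strip())
    return gene_diseases, gene_moi


def information_content(graph: OntologyGraph, ann: AnnotationSet) -> ICTable:
    """Disease-corpus information content: IC(t) = -ln(count(t)/N).

    ``count(t)`` is the number of diseases annotated to ``t`` or any of its
    descendants.  Terms with zero count receive add-one smoothing (the IC of
    a singleton term) so every similarity stays finite.
    """
    diseases = {d: set(ts) for d, ts in ann.disease_terms.items() if ts}
    n = len(diseases)
    if n == 0:
        raise OntologyError("empty disease corpus: no annotated diseases")

    counts: Dict[str, int] = {t: 0 for t in graph.terms}
    for terms in diseases.values():
        closure: Set[str] = set()
        for t in terms:
            closure |= graph.ancestors(t)
        for t in closure:
            counts[t] += 1

    ic = {
        t: -math.log(max(c, 1) / n) if n > 0 else 0.0
        for t, c in counts.items()
    }
    return ICTable(ic=ic)


def resnik(graph: OntologyGraph, ic: ICTable, t1: str, t2: str) -> float:
    """Maximum IC over the common ancestors of two terms."""
    common = graph.ancestors(t1) & graph.ancestors(t2)
    if not common:  # cannot happen in a rooted DAG, but stay defensive
        return 0.0
    return max(ic[t] for t in common)


def bma_similarity(
    g1: Sequence[str],
    g2: Sequence[str],
    graph: OntologyGraph,
    ic: ICTable,
    weights: Optional[Sequence[Optional[float]]] = None,
) -> float:
    """Best-match-average similarity between two term sets.

    With ``S`` the ``m x n`` Resnik matrix between ``g1`` and ``g2`` and
    ``w_j`` the frequency weight of ``g2[j]`` (1 when unavailable)::

        (sum_i max_j S_ij + sum_j w_j * max_i S_ij) / (m + sum_j w_j)

    which reduces to the plain row/column best-match average at unit
    weights.
    """
    g1 = [graph.resolve(t) for t in g1]
    g2 = [graph.resolve(t) for t in g2]
    if not g1 or not g2:
        raise OntologyError("bma_similarity requires non-empty term sets")
    if weights is None:
        w = [1.0] * len(g2)
    else:
        if len(weights) != len(g2):
            raise OntologyError("weights length must match g2")
        w = [1.0 if x is None else float(x) for x in weights]

    s = [[resnik(graph, ic, a, b) for b in g2] for a in g1]
    row_part = sum(max(row) for row in s)
    col_part = sum(w[j] * max(s[i][j] for i in range(len(g1))) for j in range(len(g2)))
    return (row_part + col_part) / (len(g1) + sum(w))


def _normalized(raw: float, ceiling: float) -> float:
    if ceiling <= 0.0:
        return 0.0
    return min(raw / ceiling, 1.0)


def phenotypic_score(
    patient_terms: Sequence[str],
    gene: str,
    ann: AnnotationSet,
    graph: OntologyGraph,
    ic: ICTable,
    combination: str = "max",
) -> PhenotypicScore:
    """Combined gene/condition phenotypic similarity for one gene.

    The gene score compares the patient terms with the gene's annotation
    profile; the condition score takes the best match over the gene's
    diseases using frequency-weighted BMA.  Each raw score is normalized by
    the self-similarity ceiling of the annotation side so that ``combined``
    lies in [0, 1]; a gene without any annotation scores 0 with
    ``no_annotation`` set.
    """
    if not patient_terms:
        raise OntologyError("patient term set is empty")
    if combination not in ("max", "mean"):
        raise OntologyError(f"unknown combination {combination!r}")

    gene_terms = ann.gene_terms.get(gene)
    diseases = ann.gene_diseases.get(gene, set())
    have_gene = bool(gene_terms)
    have_condition = any(ann.disease_terms.get(d) for d in diseases)
    if not have_gene and not have_condition:
        return PhenotypicScore(0.0, 0.0, 0.0, no_annotation=True)

    gene_raw = gene_norm = 0.0
    if have_gene:
        gterms = sorted(gene_terms)
        gene_raw = bma_similarity(patient_terms, gterms, graph, ic)
        gene_norm = _normalized(gene_raw, bma_similarity(gterms, gterms, graph, ic))

    cond_raw = cond_norm = 0.0
    for disease in sorted(diseases):
        weighted = ann.disease_terms.get(disease)
        if not weighted:
            continue
        dterms = sorted(weighted)
        dweights = [weighted[t] for t in dterms]
        raw = bma_similarity(patient_terms, dterms, graph, ic, weights=dweights)
        ceiling = bma_similarity(dterms, dterms, graph, ic, weights=dweights)
        norm = _normalized(raw, ceiling)
        if norm > cond_norm:
            cond_raw, cond_norm = raw, norm

    if combination == "max":
        combined = max(gene_norm, cond_norm)
    else:
        combined = (gene_norm + cond_norm) / 2.0
    return PhenotypicScore(gene_raw, cond_raw, combined, no_annotation=False)


def rank_genes_by_phenotype(
    patient_terms: Sequence[str],
    gene_list: Sequence[str],
    ann: AnnotationSet,
    graph: OntologyGraph,
    ic: ICTable,
    combination: str = "max",
) -> List[Tuple[str, PhenotypicScore]]:
    """Genes sorted by combined score descending; ties broken by gene ID.

    Unannotated genes (combined 0, flag set) naturally sort last.
    """
    if not gene_list:
        raise OntologyError("gene list is empty")
    scored = [
        (g, phenotypic_score(patient_terms, g, ann, graph, ic, combination=combination))
        for g in gene_list
    ]
    scored.sort(key=lambda gs: (-gs[1].combined, gs[0]))
    return scored
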