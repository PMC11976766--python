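import numpy as np
import pytest

from sdx.ontology import AnnotationSet, information_content, load_ontology
from sdx.simulate import make_mini_ontology
from sdx.variants import GT, Pedigree, PedigreeMember


def make_obo(parent_map, obsolete=None):
    """Render a parent map {term: [parents]} as OBO text."""
    lines = ["format-version: 1.2", ""]
    for term, parents in parent_map.items():
        lines += ["[Term]", f"id: {term}"]
        lines += [f"is_a: {p}" for p in parents]
        lines.append("")
    for term, repl in (obsolete or {}).items():
        lines += ["[Term]", f"id: {term}", "is_obsolete: true"]
        if repl:
            lines.append(f"replaced_by: {repl}")
        lines.append("")
    return "\n".join(lines)


@pytest.fixture(scope="session")
def mini():
    """Seeded 200-term ontology with 50 annotated genes."""
    return make_mini_ontology(seed=11, n_terms=200, n_genes=50)


@pytest.fixture(scope="session")
def mini_graph(mini):
    return mini.graph


@pytest.fixture(scope="session")
def mini_ic(mini):
    return mini.ic


# --- small hand-built corpus for exact IC checks -------------------------

HAND_PARENTS = {
    "HP:0000001": [],
    "HP:0000002": ["HP:0000001"],
    "HP:0000003": ["HP:0000001"],
    "HP:0000004": ["HP:0000002"],
    "HP:0000005": ["HP:0000002"],
    "HP:0000006": ["HP:0000003"],
    "HP:0000007": ["HP:0000004", "HP:0000003"],
}


@pytest.fixture(scope="session")
def hand_graph():
    return load_ontology(make_obo(HAND_PARENTS))


@pytest.fixture(scope="session")
def hand_corpus(hand_graph):
    # 4 diseases; HP:0000004 covered by D1 (directly) and D2 (via descendant 7)
    ann = AnnotationSet(
        gene_terms={"G1": frozenset({"HP:0000004", "HP:0000005"})},
        disease_terms={
            "D1": {"HP:0000004": None},
            "D2": {"HP:0000007": None},
            "D3": {"HP:0000005": None},
            "D4": {"HP:0000006": None},
        },
        gene_diseases={"G1": {"D1"}},
    )
    return ann, information_content(hand_graph, ann)


# --- pedigree builders ----------------------------------------------------


def trio_pedigree(proband_sex="male", mother_affected=False, father_affected=False):
    return Pedigree(
        members=(
            PedigreeMember("dad", "male", "affected" if father_affected else "unaffected"),
            PedigreeMember("mom", "female", "affected" if mother_affected else "unaffected"),
            PedigreeMember("kid", proband_sex, "affected", mother="mom", father="dad"),
        ),
        proband="kid",
    )


def proband_only_pedigree(sex="male"):
    return Pedigree(
        members=(PedigreeMember("kid", sex, "affected"),),
        proband="kid",
    )


def trio_genotypes(kid, mom, dad):
    return {"kid": kid, "mom": mom, "dad": dad}
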