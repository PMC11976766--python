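import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdx.ranker import (
    CandidateDiagnosis,
    FeatureVector,
    RankedList,
    assemble_features,
    binary_entropy,
    cdf_at_k,
    enumerate_candidates,
    lopo_cv,
    prediction_uncertainty,
    quality_feature,
    rank_candidates,
    train_model,
)
from sdx.variants import GT, VariantRecord

from conftest import trio_pedigree

TRIO = trio_pedigree()


def variant(pos, gene="G1", kid=GT.HET, mom=GT.HOM_REF, dad=GT.HOM_REF,
            filt="PASS", chrom="chr1"):
    return VariantRecord(
        chrom=chrom, pos=pos, ref="A", alt="G", gene=gene, filter_field=filt,
        genotypes={"kid": kid, "mom": mom, "dad": dad},
    )


def candidate(path=0.5, sim=0.5, match=0, qual=1, pos=100, gene="G1",
              label="unknown", proband="kid"):
    v = variant(pos, gene=gene)
    return CandidateDiagnosis(
        proband=proband, variants=(v,), gene=gene,
        features=FeatureVector(path, sim, match, qual), label=label,
    )


# ------------------------------------------------------------------ quality


@pytest.mark.parametrize(
    "filt,expected", [("PASS", 1), ("pass", 1), ("Pass", 1), ("LowQual", 0), (".", 0)]
)
def test_quality_feature(filt, expected):
    assert quality_feature(variant(1, filt=filt)) == expected


def test_quality_missing_configurable():
    assert quality_feature(variant(1, filt="."), missing_is_pass=True) == 1


# -------------------------------------------------------------- enumeration


def test_three_genes_three_candidates():
    records = [variant(100, "G1"), variant(200, "G2"), variant(300, "G3")]
    cands = enumerate_candidates(records, TRIO, {"G1", "G2", "G3"})
    assert len(cands) == 3
    assert all(not c.is_pair for c in cands)


def test_trans_pair_adds_candidate():
    records = [variant(100, "G1", mom=GT.HET), variant(200, "G1", dad=GT.HET)]
    cands = enumerate_candidates(records, TRIO, {"G1"})
    assert len(cands) == 3
    assert sum(c.is_pair for c in cands) == 1


def test_unannotated_gene_excluded():
    cands = enumerate_candidates([variant(100, "NOPE")], TRIO, {"G1"})
    assert cands == []


def test_enumeration_matches_combinatorial_oracle():
    rng = np.random.default_rng(6)
    records = []
    pos = 100
    for gene in ("A", "B", "C"):
        for _ in range(rng.integers(1, 5)):
            origin = rng.choice(["maternal", "paternal", "none"])
            records.append(
                variant(
                    pos, gene,
                    mom=GT.HET if origin == "maternal" else GT.HOM_REF,
                    dad=GT.HET if origin == "paternal" else GT.HOM_REF,
                )
            )
            pos += 100
    cands = enumerate_candidates(records, TRIO, {"A", "B", "C"})
    n_singles = len(records)
    n_pairs = 0
    by_gene = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)
    for gene, rs in by_gene.items():
        for a, b in itertools.combinations(rs, 2):
            def origin(v):
                if v.genotypes["mom"] == GT.HET:
                    return "M"
                if v.genotypes["dad"] == GT.HET:
                    return "F"
                return "DN"
            oa, ob = origin(a), origin(b)
            if oa != ob or oa == "DN":
                n_pairs += 1
    assert len(cands) == n_singles + n_pairs


# ----------------------------------------------------------------- features


def test_singleton_feature_passthrough():
    v = variant(100, mom=GT.HOM_REF, dad=GT.HOM_REF)  # de novo
    cand = CandidateDiagnosis(proband="kid", variants=(v,), gene="G1")
    out = assemble_features(cand, 0.8, {v.key: 0.99}, TRIO, {"AD"})
    assert out.features == FeatureVector(0.99, 0.8, 1, 1)
    assert out.segregation.pattern == "de_novo"


def test_pair_min_and_aggregation():
    v1 = variant(100, mom=GT.HET)
    v2 = variant(200, dad=GT.HET, filt="LowQual")
    cand = CandidateDiagnosis(proband="kid", variants=(v1, v2), gene="G1")
    out = assemble_features(cand, 0.5, {v1.key: 0.9, v2.key: 0.4}, TRIO, {"AR"})
    assert out.features.pathogenicity == pytest.approx(0.4)
    assert out.features.quality == 0
    assert out.features.inheritance_match == 1
    assert out.segregation.pattern == "ar_compound_het"


def test_missing_component_is_hard_error():
    v = variant(100)
    cand = CandidateDiagnosis(proband="kid", variants=(v,), gene="G1")
    with pytest.raises(KeyError, match="pathogenicity"):
        assemble_features(cand, 0.5, {}, TRIO, {"AD"})


# ----------------------------------------------------------------- training


def separable_candidates(n=80, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        causative = i % 8 == 0
        out.append(
            candidate(
                path=rng.uniform(0.8, 1.0) if causative else rng.uniform(0.0, 0.2),
                sim=rng.uniform(0.7, 1.0) if causative else rng.uniform(0.0, 0.3),
                match=int(causative),
                qual=1,
                pos=100 + i,
                label="causative" if causative else "non_causative",
            )
        )
    return out


@pytest.mark.parametrize("kind", ["ensemble", "linear", "bayes", "mlp"])
def test_separable_training_accuracy(kind):
    cands = separable_candidates()
    model = train_model(cands, model_kind=kind, seed=0)
    x = np.vstack([c.features.as_array() for c in cands])
    y = np.array([c.label == "causative" for c in cands])
    assert (model.predict_proba(x) > 0.5).astype(bool).tolist() == y.tolist()


def test_training_determinism():
    cands = separable_candidates()
    x = np.vstack([c.features.as_array() for c in cands])
    p1 = train_model(cands, "ensemble", seed=3).predict_proba(x)
    p2 = train_model(cands, "ensemble", seed=3).predict_proba(x)
    assert np.array_equal(p1, p2)


def test_single_class_is_error():
    cands = [candidate(label="non_causative", pos=i + 1) for i in range(5)]
    with pytest.raises(ValueError):
        train_model(cands)


# ------------------------------------------------------------------ ranking


def test_rank_order_by_probability():
    cands = separable_candidates(n=24, seed=5)
    model = train_model(cands, "linear", seed=0)
    ranked = rank_candidates(model, cands)
    probs = [c.predicted_probability for c in ranked.candidates]
    assert probs == sorted(probs, reverse=True)
    assert [c.rank for c in ranked.candidates] == list(range(1, 25))


def test_rank_matches_sort_oracle():
    cands = separable_candidates(n=40, seed=9)
    model = train_model(cands, "linear", seed=0)
    ranked = rank_candidates(model, cands)
    x = np.vstack([c.features.as_array() for c in cands])
    p = model.predict_proba(x)
    oracle = sorted(
        zip(cands, p),
        key=lambda cp: (
            -cp[1],
            -cp[0].features.pathogenicity,
            -cp[0].features.phenotypic_similarity,
            cp[0].sort_coordinate,
        ),
    )
    assert [c.variant_ids for c, _ in oracle] == [
        c.variant_ids for c in ranked.candidates
    ]


def test_tie_break_deterministic():
    cands = [candidate(path=0.5, sim=0.5, pos=p) for p in (300, 100, 200)]
    labeled = separable_candidates()
    model = train_model(labeled, "linear", seed=0)
    orders = [
        [c.variant_ids for c in rank_candidates(model, cands).candidates]
        for _ in range(3)
    ]
    assert orders[0] == orders[1] == orders[2]
    positions = [int(v.split(":")[1]) for v in orders[0]]
    assert positions == sorted(positions)


def test_rank_monotone_under_irrelevant_insertion():
    cands = separable_candidates(n=30, seed=11)
    model = train_model(cands, "linear", seed=0)
    before = [c.variant_ids for c in rank_candidates(model, cands).candidates]
    extra = candidate(path=0.01, sim=0.01, match=0, qual=0, pos=99999)
    after = [c.variant_ids for c in rank_candidates(model, cands + [extra]).candidates]
    after_without = [v for v in after if v != extra.variant_ids]
    assert after_without == before


# --------------------------------------------------------------------- lopo


def make_cohort(n_probands=5, n_variants=30, seed=0):
    rng = np.random.default_rng(seed)
    cohort = {}
    for p in range(n_probands):
        pid = f"P{p}"
        cands = []
        for i in range(n_variants):
            causative = i == 0
            cands.append(
                candidate(
                    path=rng.uniform(0.85, 1.0) if causative else rng.uniform(0, 0.3),
                    sim=rng.uniform(0.7, 1.0) if causative else rng.uniform(0, 0.4),
                    match=int(causative),
                    qual=1,
                    pos=1000 * p + i + 1,
                    label="causative" if causative else "non_causative",
                    proband=pid,
                )
            )
        cohort[pid] = cands
    return cohort


def test_lopo_counts_and_ranks():
    cohort = make_cohort(5)
    res = lopo_cv(cohort, "linear", seed=0)
    assert res.n_models == 5
    assert len(res.causative_ranks) == 5


def test_lopo_no_leakage():
    cohort = make_cohort(4)
    res = lopo_cv(cohort, "linear", seed=0)
    for pid, ranked in res.ranked_lists.items():
        test_ids = {c.variant_ids for c in ranked.candidates}
        train_ids = {
            c.variant_ids for other, cands in cohort.items() if other != pid
            for c in cands
        }
        assert test_ids.isdisjoint(train_ids)
        assert all(c.proband == pid for c in ranked.candidates)


def test_lopo_separable_median_rank_one():
    cohort = make_cohort(20, seed=2)
    res = lopo_cv(cohort, "linear", seed=0)
    ranks = sorted(res.causative_ranks.values())
    assert ranks[len(ranks) // 2] == 1


def test_lopo_excludes_probands_without_causative():
    cohort = make_cohort(3)
    cohort["orphan"] = [candidate(label="non_causative", pos=5)]
    res = lopo_cv(cohort, "linear", seed=0)
    assert "orphan" not in res.causative_ranks
    assert res.n_models == 3


# ------------------------------------------------------------------- cdf@k


def test_cdf_examples():
    assert cdf_at_k([1, 1, 2, 12], 1) == pytest.approx(0.5)
    assert cdf_at_k([1, 1, 2, 12], 12) == pytest.approx(1.0)


def test_cdf_counting_oracle():
    rng = np.random.default_rng(1)
    ranks = [int(r) for r in rng.integers(1, 36, size=35)]
    for k in (1, 5, 10, 35):
        assert cdf_at_k(ranks, k) == sum(1 for r in ranks if r <= k) / len(ranks)


def test_cdf_monotone_in_k():
    ranks = [3, 1, 7, 2, 2, 9]
    values = [cdf_at_k(ranks, k) for k in range(1, 12)]
    assert values == sorted(values)


def test_cdf_errors():
    with pytest.raises(ValueError):
        cdf_at_k([], 1)
    with pytest.raises(ValueError):
        cdf_at_k([1], 0)


# ------------------------------------------------------------- uncertainty


def test_uncertainty_degenerate_members():
    assert prediction_uncertainty([1.0, 1.0, 1.0]) == (0.0, 0.0, 0.0)


def test_uncertainty_single_half():
    total, aleatoric, epistemic = prediction_uncertainty([0.5])
    assert total == pytest.approx(1.0)
    assert epistemic == pytest.approx(0.0)


def test_uncertainty_two_member_closed_form():
    total, aleatoric, epistemic = prediction_uncertainty([0.2, 0.8])
    assert total == pytest.approx(1.0)
    assert aleatoric == pytest.approx(binary_entropy(0.2), abs=1e-12)
    assert aleatoric == pytest.approx(0.7219, abs=1e-4)
    assert epistemic == pytest.approx(1.0 - 0.7219280948873623, abs=1e-12)


@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
@settings(max_examples=300, deadline=None)
def test_epistemic_nonnegative(probs):
    total, aleatoric, epistemic = prediction_uncertainty(probs)
    assert epistemic >= 0.0
    if len(set(probs)) == 1:
        assert total == pytest.approx(aleatoric, abs=1e-12)


def test_uncertainty_rejects_out_of_range():
    with pytest.raises(ValueError):
        prediction_uncertainty([1.2])
    with pytest.raises(ValueError):
        prediction_uncertainty([])
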