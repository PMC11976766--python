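# sdx — suggested-diagnosis ranking for rare-disease families

`sdx` ranks every candidate genetic diagnosis in a proband's multi-sample
VCF — single variants and compound-heterozygous pairs — by the predicted
probability of being disease-causing. Each candidate carries exactly four
features:

1. **Pathogenicity** — a documented 14-criterion evidence rule table
   (PVS1 … BP6) mapped to a probability by a logistic model, plus the
   standard five-tier class.
2. **Phenotypic similarity** — Resnik term similarity over an HPO-style
   ontology, combined with a frequency-weighted best-match-average into a
   normalized gene/condition score.
3. **Inheritance match** — family segregation inferred under complete
   penetrance (de novo, recessive homozygous, compound het, isodisomy,
   X-linked hemizygous, Y-linked) matched against the gene's expected mode
   of inheritance.
4. **Quality** — 1 iff the VCF FILTER field is PASS.

Probabilistic rankers (random-forest ensemble, logistic, naive Bayes, MLP)
are trained on labeled cohorts and evaluated with leave-one-proband-out
cross-validation (CDF@K of the causative's rank). Ensemble-member entropy
decomposes predictive uncertainty into aleatoric and epistemic parts, and a
border-based density-principle score (`rel(x) = 1 − m_x/m`) quantifies
pointwise reliability of each prediction.

A fully self-contained simulator (`sdx.simulate`) generates the mini
ontology, gene/disease annotation corpora and family VCF/PED/HPO bundles
with a planted causative under any supported inheritance pattern — every
test and the acceptance report run offline from these.

## Layout

| module | contents |
| --- | --- |
| `sdx.ontology` | OBO parsing, annotation loaders, IC, Resnik, BMA, phenotypic score, gene ranking |
| `sdx.variants` | VCF/PED readers, allele decomposition, AF/artifact filters, cohort allele counting |
| `sdx.pathogenicity` | criteria rule table, logistic pathogenicity score, five-tier class |
| `sdx.inheritance` | segregation inference, compound-het pairing, MOI matching |
| `sdx.ranker` | candidate enumeration, feature assembly, models, LOPO CV, CDF@K, uncertainty |
| `sdx.reliability` | training borders, would-become-border counting, reliability statistics |
| `sdx.simulate` | synthetic ontology/annotation/cohort generator |
| `sdx.pipeline` | end-to-end per-family analysis |
| `sdx.cli` | `sdx` command-line entry point |

## CLI

```sh
# write a synthetic cohort (OBO, annotation TSVs, per-family VCF/PED/HPO/truth)
sdx simulate --seed 1 --n-probands 5 --variants-per-proband 200 --outdir cohort/

# rank one family's candidates
sdx rank --vcf cohort/FAM000.vcf --ped cohort/FAM000.ped \
    --hpo "$(tr '\n' ',' < cohort/FAM000.hpo.txt | sed 's/,$//')" \
    --obo cohort/ontology.obo --gene2pheno cohort/gene2pheno.tsv \
    --disease2pheno cohort/disease2pheno.tsv --moi cohort/gene2disease.tsv \
    --out ranked.tsv

# leave-one-proband-out CV / reliability summary on a simulated cohort
sdx lopo --seed 1 --n-probands 10 --variants-per-proband 300
sdx reliability --seed 1 --n-probands 10 --variants-per-proband 300
```

Every threshold (AF filter, cohort artifact allele cap, criteria cut-offs,
score combination rule, FILTER "." handling) can be overridden with a
YAML/JSON config file passed via `--config` (see `sdx.config.Settings`).

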