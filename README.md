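# acceptmap

Acceptability mapping and scoring of (pediatric) medicines from
standardized observer-reported intake questionnaires.

## The problem

Whether a child can and will take a medicine as intended — and whether a
caregiver can administer it — drives adherence, and through adherence the
safety and efficacy of treatment. *Acceptability* is multi-faceted: it
shows up in whether the dose was fully taken, the patient's reaction, how
long preparation and administration took, and in the work-arounds used to
get the dose down (dividing it, mixing with food or drink, altering the
dosage form, reaching for a syringe or dropper not provided with the
product, rewards, restraint). `acceptmap` implements a data-driven
scoring pipeline that turns such standardized observer reports — nine
categorical observational variables, 21 categories in total, per observed
intake — into a position on a reference *acceptability map* and a binary
accepted / not-accepted classification.

It is aimed at formulation scientists and clinical teams running
observational acceptability studies, and at methodologists who want the
mapping/scoring machinery (MCA, HCPC, v-tests, barycentric confidence
ellipses, exact r×c tests) as reusable, tested components.

## The method

1. **Reference map (MCA).** The evaluations of a large reference corpus
   are one-hot encoded into the complete disjunctive table Z (N × 21,
   Q = 9 variables). Correspondence analysis of Z — masses
   r_i = 1/N, c_j = colsum(Z)/(NQ), SVD of
   D_r^{-1/2}(P − rc′)D_c^{-1/2} — yields principal coordinates for
   evaluations and categories; the first three dimensions form the 3D
   acceptability map. Total inertia is J/Q − 1 = 4/3.
2. **Zones (HCPC + v-tests).** Ward clustering on the map coordinates,
   consolidated by k-means, splits the corpus into two profiles. Each
   cluster is characterized by the observed measures over-represented in
   it (hypergeometric v-test, |v| > 1.96); the cluster enriched for
   positively connoted measures is the **green** ("Positively accepted")
   zone, the other **red**. Any map point takes the zone of its nearest
   consolidated centroid.
3. **Scoring.** A medicine's evaluations are projected as supplementary
   individuals (transition formula, no influence on the map) and
   summarized by their **barycenter** plus a 90% confidence ellipse of
   the mean in each dimension pair (1–2, 1–3, 2–3):
   {x : (x − m)′(S/n)^{-1}(x − m) ≤ q}, with q the Hotelling-T²
   quantile 2(n−1)/(n−2)·F₂,ₙ₋₂(0.90). The medicine is **accepted** iff
   barycenter and all three ellipse boundaries lie in green; scores with
   n < 30 patients are flagged unreliable. Two scores differ
   significantly iff their ellipses are disjoint in every pair.
4. **Missing data.** Missing cells are imputed by regularized iterative
   MCA (fit → shrunken rank-S reconstruction → overwrite missing cells →
   renormalize), which uses both similarities between evaluations and
   relationships between the nine variables.
5. **Descriptive/inferential tables.** Per-variable contingency tables
   over time or age groups, with Pearson's χ² when ≥80% of expected
   counts are ≥5 (and none zero), otherwise the Freeman–Halton exact
   r×c test by full enumeration.

Because the multi-country reference corpus behind the published
framework is not shareable, `acceptmap.simulate` generates corpora with
planted two-profile structure (latent labels retained) so the entire
pipeline is testable end to end; `acceptmap.datasets` ships the published
summary tables of a cefaclor fine-granules study for the descriptive
layer.

## Worked example

```python
from acceptmap import (CorpusConfig, ReferenceFramework, generate_medicine,
                       generate_reference, scores_differ)

corpus = generate_reference(CorpusConfig(n_evaluations=2611, seed=42))
framework = ReferenceFramework().fit(corpus)
print(framework.mca_.eigenvalues_[:3].round(4))   # [0.4276 0.1149 0.1126]
print(framework.partition_.profile_names)
# {0: 'Positively accepted', 1: 'Negatively accepted'}  (sizes 1604 / 1007)

medicine = generate_medicine(n_patients=58, timepoints=(1, 2, 3), seed=7)
score = framework.score(medicine)
print(score.n, score.zone, score.accepted, score.reliable)
# 174 green True True
print(score.barycenter.round(3))                  # [-0.491 -0.013 -0.023]

t1 = framework.score(medicine, where={"timepoint": 1})
t3 = framework.score(medicine, where={"timepoint": 3})
print(scores_differ(t1, t3))                      # False
```

The first map dimension opposes trouble-free intakes to problematic
ones, so a well-accepted medicine lands far on the green side
(barycenter ≈ −0.49 on dim 1 here); its 174 evaluations give tight
ellipses that stay within the green zone, hence `accepted=True`. The two
timepoint scores overlap on every pane — acceptability did not change
significantly over time.

The same pipeline is scriptable from a shell:

```bash
acceptmap simulate --seed 42 --out-reference ref.csv --out-medicine med.csv
acceptmap build-framework --reference ref.csv --out framework.json
acceptmap score --framework framework.json --medicine med.csv \
    --out score.json --by timepoint --by age_group
acceptmap report --input med.csv --out-prefix med
```

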