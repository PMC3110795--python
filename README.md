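# strmix

Population-genetic analysis of multi-allelic STR (microsatellite) genotypes
for two-species contact systems with sex-biased introgression — the situation
exemplified by African forest and savanna elephants, where maternally
inherited mtDNA crosses the species boundary while the nuclear genome stays
partitioned. The package is aimed at conservation geneticists and wildlife
forensics: it quantifies nuclear population structure, measures how far
mtDNA-clade geography departs from it, and ranks STR loci for geographic
assignment panels (e.g. tracing confiscated ivory).

## What it computes

- **Bayesian admixture clustering** (`strmix.admixture`): a Gibbs sampler for
  the classic admixture model. Individual *i* carries an ancestry vector
  *q<sub>i</sub>* ~ Dirichlet(α) over *K* clusters; each allele copy has a
  latent origin *z* ~ Categorical(*q<sub>i</sub>*) and the allele is drawn
  from the origin cluster's locus frequency vector *p<sub>kl</sub>* ~
  Dirichlet(λ). Replicate runs are label-aligned, the model log-probability
  is estimated as L̂ = mean(trace) − var(trace)/2, and the number of clusters
  is chosen by the second-difference statistic
  ΔK = mean<sub>r</sub>|L″(K, r)| / sd<sub>r</sub>(L(K, r)).
- **Ordination and trees** (`strmix.ordination`): correspondence analysis of
  the individuals × alleles dosage table (chi-square-metric SVD), the
  Cavalli-Sforza & Edwards chord distance
  d = √(2(1 − Σ<sub>j</sub>√(p<sub>Aj</sub>p<sub>Bj</sub>))) combined across
  loci by root-mean-square, and Saitou–Nei neighbor joining of locale
  distance matrices.
- **Marker informativeness** (`strmix.informativeness`): per-locus Shannon
  Information Content profiles,
  SIC(m) = H(m·p₁ + (1−m)·p₂) − [m·H(p₁) + (1−m)·H(p₂)] in bits, the mutual
  information between an allele and its population of origin at admixture
  proportion m; locus ranking by peak SIC; and likelihood-based assignment
  accuracy of chosen locus panels.
- **Mito-nuclear discordance** (`strmix.mitonuclear`): per-locale mtDNA clade
  proportions, deviation of nuclear cluster means from the clade-proportion
  diagonal, and an exact (log-gamma hypergeometric enumeration) two-tailed
  2×2 test of clade presence against habitat class.
- **Locus QC** (`strmix.qc`): Monte-Carlo exact Hardy–Weinberg tests
  (conditional genotype-array probability statistic), homozygote-excess
  null-allele estimates r = (He − Ho)/(1 + He), and permutation G-tests for
  inter-locus association.
- **Synthetic data with ground truth** (`strmix.simulate`): two gene pools
  drifted apart under a Balding–Nichols Dirichlet model, forest / savanna /
  mixed locales, constructed hybrid lineages whose minor-species ancestry is
  (1/2)^(g+1) after g backcrosses, and sex-biased mtDNA introgression
  (F-clade carried by ~20% of pure savanna individuals, S-clade structurally
  absent from forest locales).
- **I/O** (`strmix.io`): STRUCTURE (two-row and two-column layouts) and
  GenePop text formats, fragment-size binning onto a repeat-motif ladder,
  and per-locus summaries.

## Worked example

```python
import numpy as np
from strmix import (SimConfig, simulate_dataset, AdmixtureModelSpec,
                    gibbs_admixture, evanno_delta_k, best_k,
                    mean_cluster_by_locale, locale_summaries,
                    habitat_association, population_freqs, rank_loci)

cfg = SimConfig(individuals_per_locale=12, seed=42)
matrix, table, truth = simulate_dataset(cfg)
print(f"{matrix.n_individuals} individuals x {matrix.n_loci} loci, "
      f"{table.locale.nunique()} locales")

runs = {K: [gibbs_admixture(matrix, AdmixtureModelSpec(
            K=K, sweeps=300, burnin=100, seed=10*K+r, infer_alpha=True)).L_hat
            for r in range(3)] for K in (1, 2, 3)}
print("best K:", best_k(evanno_delta_k(runs)))

est = gibbs_admixture(matrix, AdmixtureModelSpec(
    K=2, sweeps=300, burnin=100, seed=7, infer_alpha=True))
locale_q = mean_cluster_by_locale(est, table)
print(locale_q.head(3).round(3).to_string(index=False))

t = table.set_index("individual_id")
labels = {i: ("forest" if t.at[i, "habitat"] == "forest" else "savanna")
          for i in matrix.individual_ids}
freqs, _ = population_freqs(matrix, labels)
print(rank_loci(freqs["forest"], freqs["savanna"]).head(3)
      .round(3).to_string(index=False))

summaries = locale_summaries(table, locale_q, savanna_col="q_2")
tab, p = habitat_association(summaries)
print("habitat x S-clade:", tab.tolist(), "p =", f"{p:.2e}")
```

This prints:

```
276 individuals x 12 loci, 23 locales
best K: 2
locale   q_1   q_2  n
   F01 0.001 0.999 12
   F02 0.001 0.999 12
   F03 0.005 0.995 12
locus  m_star  sic_star
  L06    0.52     0.766
  L11    0.53     0.601
  L05    0.46     0.450
habitat x S-clade: [[0, 17], [5, 1]] p = 1.78e-04
```

Reading the output: ΔK picks two clusters; the forest locales (F01–F03
shown) assign ≥99.5% to one cluster (cluster labels are arbitrary per run —
here cluster 2 happens to track forest ancestry); locus L06 is the most
informative marker for telling the two pools apart, carrying up to 0.77
bits per allele near even admixture; and S-clade mtDNA presence is
significantly associated with habitat (absent from all 5 forest locales,
present at 17 of 18 others).

The same pipeline runs from the shell:

```bash
strmix simulate --out demo --seed 42
strmix run --config demo_config.yaml --out demo_run
```

where the config names either a generator block (`simulate: {...}`) or input
files, plus stage toggles, a K range and seeds. Every run writes a
`manifest.json` with the config hash so outputs are reproducible
byte-for-byte.

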