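# gptrainsel

Training-set construction and benchmarking for genomic prediction in
structured genotype panels.

## The problem

Genomic prediction fits a model on a *training set* of genotyped and
phenotyped lines and predicts the genotypic values of the remaining
*validation set*. When the calibration panel is structured — subpopulations,
sibling families, unique accessions — a randomly drawn training set covers
the genetic space unevenly: dense regions are oversampled, sparse regions
and isolated lines end up far from every training entry, and predictive
ability suffers. This package implements and benchmarks five training-set
construction methods on identity-by-state (IBS) genetic distance:

| Method | Idea |
|--------|------|
| **U**  | Uniform coverage: sample a genotype at random, discard all candidates within a sampling radius *r* (distance = 1 − IBS), repeat until the panel is exhausted |
| **SU** | Stratified-uniform: as U, but a candidate inside the radius survives if it belongs to a different subpopulation, so every stratum keeps at least one entry |
| **CD** | Exchange optimization of the mean generalized coefficient of determination of the validation contrasts |
| **S**  | Stratified random sampling with log-proportional allocation, *n*<sub>t,s</sub> = *n*<sub>t</sub> log *n*<sub>s</sub> / Σ log *n*<sub>s</sub> |
| **R**  | Simple random sampling |

and four prediction models sharing one REML/BLUP mixed-model engine:

* **QTL** — random effect per detected QTL marker, each with its own variance;
* **GBLUP** — *y* = μ + *G* + *e*, *G* ~ N(0, **A** σ²<sub>g</sub>) with the
  realized additive relationship
  *A*<sub>ij</sub> = (1/K) Σ<sub>k</sub> (G<sub>ik</sub> − 2p<sub>k</sub>)(G<sub>jk</sub> − 2p<sub>k</sub>) / 2p<sub>k</sub>(1−p<sub>k</sub>);
* **QGBLUP** — GBLUP plus explicit QTL terms, with the polygenic kinship
  recomputed after masking markers within ±20 cM of each QTL;
* **RKHS** — Gaussian kernel **A\*** = exp(−**D**/θ), θ tuned on a grid in
  [0.05, 5] by cross-validation inside the training set.

QTL enter via a mixed-model GWAS with leave-one-chromosome-out kinship and a
genome-wide 0.01 threshold from the Li–Ji effective number of tests.
Population structure is characterized by IBS-PCA, a Tracy–Widom count of
significant components (subpopulations = count + 1), k-means assignment, and
the Weir–Cockerham Fst. Predictive ability is the Pearson correlation between
observed and predicted phenotypes in the validation set, aggregated over
independent realizations on Fisher's z scale.

A synthetic-data module generates structured inbred panels with known truth
(hierarchical Balding–Nichols model: subpopulations at a target Fst, sibling
families and unique accessions within them) so the whole pipeline is testable
without external data.

## Worked example

```python
import gptrainsel as gt

cfg = gt.SyntheticPanelConfig(seed=11)          # 250 lines, 5 subpops, Fst 0.25
panel, assignment, trait, qtl, g = gt.simulate_dataset(cfg)
print(f"panel: {panel.n_genotypes} genotypes x {panel.n_markers} markers, "
      f"{assignment.S} subpopulations")
print(f"Weir-Cockerham Fst: {gt.fst_weir_cockerham(panel, assignment):.3f}")

k_ibs = gt.ibs_matrix(panel)
a = gt.additive_relationship(panel)
radius = gt.find_radius(k_ibs, 200)
print(f"U sampling radius for size 200: {radius:.4f}")

for method in ("U", "CD", "R"):
    rs = []
    for i in range(10):
        if method == "U":
            sp = gt.sample_uniform(k_ibs, 200, seed=i, radius=radius)
        elif method == "CD":
            sp = gt.sample_cd(a, 200, h2=0.7, seed=i)
        else:
            sp = gt.sample_random(k_ibs.genotype_ids, 200, seed=i)
        fit = gt.fit_prediction_model("GBLUP", trait, panel, sp.training_ids, A=a)
        rs.append(gt.predictive_ability(fit.predictions, trait, sp.validation_ids))
    mean_r, se = gt.fisher_aggregate(rs)
    print(f"{method:>3}: mean predictive ability {mean_r:.3f} (SE_z {se:.3f})")
```

prints

```
panel: 250 genotypes x 2000 markers, 5 subpopulations
Weir-Cockerham Fst: 0.275
U sampling radius for size 200: 0.0953
  U: mean predictive ability 0.632 (SE_z 0.028)
 CD: mean predictive ability 0.701 (SE_z 0.029)
  R: mean predictive ability 0.493 (SE_z 0.039)
```

The realized panel Fst (0.275) sits slightly above the 0.25 subpopulation
target because sibling families add within-subpopulation differentiation.
Training sets that cover the genetic space (U) or maximize contrast
reliability (CD) beat random sampling by 0.14 and 0.21 here: with 80 % of
the panel in training, random sampling still leaves some validation
genotypes without any close training relative, while U places every
isolated line in the training set and validates only well-covered ones.

## Command line

```bash
gp-trainsel simulate --seed 3 --out demo/
gp-trainsel structure --panel demo/panel.csv --map demo/map.csv --out demo/structure/
gp-trainsel split --panel demo/panel.csv --map demo/map.csv --method U --size 200 --out demo/split/
gp-trainsel experiment --config experiment.yaml --out demo/results/
```

`experiment` consumes a YAML config (panel paths or a `synthetic:` block,
method/model/size grids, realization count, seed) and writes summary,
per-realization and within-subpopulation ability tables, each stamped with
the config hash and seed.

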