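# ossa

Cross-bone single-cell divergence statistics: does one bone-marrow
compartment — the skull calvaria, say — transcriptionally diverge from the
other bones?

`ossa` is a Python library (plus a thin `ossa` CLI) for comparing
single-cell RNA-seq profiles across anatomical regions under several
conditions (naive / sham / MCAo stroke model).  It provides, as
construct-then-`fit()` model objects with tabular results:

- **`PCDivergence`** — an eigenvalue-weighted PC-regression divergence
  score per (cell type, region).  For a one-region-vs-rest indicator *y*
  and a PCA of the cell-type population with scores *s<sub>j</sub>* and
  eigenvalues *λ<sub>j</sub>*,

  *V* = Σ<sub>j</sub> R²<sub>j</sub> λ<sub>j</sub> / Σ<sub>j</sub> λ<sub>j</sub>,  R²<sub>j</sub> = corr(*s<sub>j</sub>*, *y*)²,

  with a label-permutation null (1000 shuffles; significant ⇔ no permuted
  score reaches the observed one).
- **`GapSplitDE`** — a combinatorial differential-expression test: regions
  ordered by a gene's mean expression are split at the largest gap; a
  Welch t-test on the two groups and one on the two boundary regions are
  combined by max-p / min-log2-fold-change, thresholded at p < 0.05 and
  LFC > 1.
- **`LRPermutationModel`** — a CellPhoneDB-style ligand-receptor
  permutation analysis with balanced per-type sampling (400 cells/type),
  significance at p = 0 under 1000 joint label shuffles, and cross-region
  *common* / *unique* calls (unique: p = 0 in one region and p > 0.95 in
  every other).

Around these sit the supporting stages: tissue-class-aware quality control,
cluster-based size factors and log-normalization, per-sample highly
variable gene selection, region dendrograms on averaged principal
components, inflammation gene-set scores, grouped t-tests with
Benjamini-Hochberg, and a proportion-vs-flow-cytometry correlation — plus a
fully seeded synthetic cohort generator with planted ground truth
(expression shifts and ligand-receptor elevations) for recovery testing.
See `docs/methods.md` for the models, conventions and limitations.

## Worked example

Simulate four bones with 25 genes planted 4-fold up in the calvaria, run
QC → normalization → divergence → DE:

```python
import numpy as np
from ossa import (SimulationConfig, PlantedEffect, simulate_cohort, apply_qc,
                  cluster_for_size_factors, compute_size_factors, log_normalize,
                  select_hvgs, PCDivergence, GapSplitDE)

sim = SimulationConfig(
    n_regions=4, n_conditions=1, n_cell_types=2, cells_per_sample=400,
    n_genes=600, region_labels=["calvaria", "femur", "humerus", "vertebra"],
    seed=0,
)
effects = [PlantedEffect(f"g{i:04d}", "calvaria", log2_fold=2.0) for i in range(25)]
cohort, truth = simulate_cohort(sim, effects)

filtered, report = apply_qc(cohort)
clusters = cluster_for_size_factors(filtered, seed=0)
layer = log_normalize(filtered, compute_size_factors(filtered, clusters))
hvgs = select_hvgs(layer, filtered.cells["sample_id"], n_per_sample=400)

res = PCDivergence(layer, filtered.cells["region"].to_numpy(),
                   filtered.cells["cell_type"].to_numpy(),
                   genes=hvgs.genes).fit(n_perm=1000, seed=1)
print(res.summary())
de = GapSplitDE(layer, filtered.cells["region"].to_numpy(),
                filtered.cells["cell_type"].to_numpy()).fit()
print(de.summary())
```

Output:

```
PC-regression divergence (one region vs rest)
==============================================
        type_0    calvaria  V=0.1978  p=0 (n_in=204) *
        type_0       femur  V=0.0238  p=0 (n_in=202) *
        type_0     humerus  V=0.0234  p=0 (n_in=193) *
        type_0    vertebra  V=0.0226  p=0 (n_in=205) *
        type_1    calvaria  V=0.1731  p=0 (n_in=196) *
        type_1       femur  V=0.0194  p=0 (n_in=198) *
        type_1     humerus  V=0.0195  p=0 (n_in=207) *
        type_1    vertebra  V=0.0207  p=0 (n_in=195) *
* significant: no permutation reached the observed score
Gap-split combinatorial DE
==========================
genes tested: 600  strata: 2  DEG calls: 50 (p < 0.05, LFC > 1)
      calvaria: 50 up / 0 down
         femur: 0 up / 50 down
       humerus: 0 up / 50 down
      vertebra: 0 up / 50 down
```

The calvaria's divergence score (V ≈ 0.19) is roughly eight times the other
bones' — and the gap-split test recovers exactly the 25 planted genes in
each of the two cell-type strata, all attributed to the calvaria as the
high group.  (The other bones also reach p = 0 here because in a
one-vs-rest contrast their "rest" contains the shifted calvaria; on null
cohorts the permutation p-values are uniform.)

The same pipeline runs end to end from the shell:

```sh
ossa run-all --out my_run --seed 7        # simulate → qc → divergence → de → lr
ossa simulate --out cohort --seed 7       # or stage by stage
ossa qc --in cohort --out filtered
ossa divergence --in filtered --n-perm 1000 --seed 7 --out divergence.tsv
```

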