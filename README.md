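# pairconn

Learned pairwise-attention functional-connectivity networks for
predicting longitudinal, multi-label clinical outcomes from
parcellated fMRI time series.

## The problem

Prospective psychiatric cohorts ask whether a single brain scan taken
shortly after an index event can predict a patient's clinical course
months later: diagnosis status at several follow-up time-points,
symptom-cluster profiles, and whether early symptoms persist.  The
input is one matrix per subject — N atlas-defined regions × T BOLD
samples — and the outputs are small binary label vectors with missing
follow-ups.  `pairconn` implements an end-to-end network for this
setting, together with everything needed to exercise it without
clinical data: a synthetic-cohort generator, cross-validated
evaluation, DSM-5 symptom-cluster utilities, and FDR-corrected
edge-wise group statistics.

## The model

For a scan x = (s_1, …, s_N), s_i ∈ R^T:

1. e_i = E(s_i) — a shared six-layer 1-D CNN embeds each regional
   series (d = 32 by default);
2. k_ij = F([e_i, e_j]) — a shared MLP with terminal sigmoid scores
   every ordered region pair, giving the connectivity matrix
   K ∈ [0,1]^{N×N};
3. w_i = β + (1 − β) Σ_{j≠i} k_ij — pairwise attention aggregates each
   region's outgoing scores (β = 0.9);
4. e_i′ = w_i e_i — embeddings are reweighted;
5. k′_ij = F([w_i e_i, w_j e_j]) — the same F produces the updated
   matrix K′;
6. ŷ = C(flatten(K′)) — an MLP classifier outputs l logits
   (l = 3 diagnosis time-points, l = 20 symptoms, l = 1 persistence).

Training minimizes L = λ·L1 + (1 − λ)·L2 (λ = 0.6), where L1 and L2
are masked, class-weighted BCE losses from applying the shared
classifier to K and K′ respectively; inference uses the K′ path.
Ablation switches reproduce the identity-E, Pearson-F,
no-reweighting and independent-per-time-point variants.  Edge-wise
group differences are two-sample t-tests on symmetrized k′ entries
with Benjamini–Hochberg correction.

All numerics run on a small reverse-mode autodiff engine over numpy
(gradients verified against finite differences in the test suite);
runs are bit-reproducible given a seed.

## Worked example

Generate a 60-subject synthetic cohort whose group signal lives purely
in the coupling of two planted region pairs, train the joint
three-time-point diagnosis head with the reduced desk-scale network,
and evaluate on held-out subjects:

```python
import pairconn as pc
from pairconn.presets import desk_model_config, desk_train_config

cohort = pc.generate_cohort(pc.CohortConfig(
    n_subjects=120, n_regions=8, n_timepoints_signal=64,
    prevalence_t1=0.5, prevalence_t2=0.5, prevalence_t3=0.5,
    planted_pairs=[(0, 1), (2, 3)], effect_strength=4.0,
    dropout_t2=0.0, dropout_t3=0.0, seed=7))
ds = cohort.to_dataset()

mc = desk_model_config(n_regions=8, n_timepoints=64)
tc = desk_train_config(seed=7, n_splits=2)
res = pc.cross_validate(ds, mc, tc, head="dx")
print(res.report.summary()[["head", "accuracy_mean", "auc_mean"]])
```

prints (mean over the two held-out splits):

```
  head  accuracy_mean  auc_mean
0   t1       0.833333  0.906190
1   t2       0.812500  0.902694
2   t3       0.812500  0.898990
```

so even this small cohort (120 subjects, 8 regions) yields held-out
AUC ≈ 0.9 purely from pairwise coupling — the series are z-scored, so
no marginal feature separates the groups; the three time-point heads
nearly coincide because the cohort was generated with persistent
labels.  The edge-wise statistics then localize the signal:

```python
from pairconn.edge_stats import collect_edges, edge_ttests
import numpy as np

test_ids = res.splits[0][1]
sub = ds.subset(test_ids)
y = np.array([sub.labels[i].dx[0] for i in sub.subject_ids])
report = edge_ttests(collect_edges(res.models[0], sub.subjects), y,
                     region_names=ds.region_names)
print(report.head(3)[["name_i", "name_j", "t", "p_adj", "significant"]])
```

```
    name_i   name_j         t     p_adj  significant
0  roi_002  roi_003  5.566700  0.000378         True
1  roi_000  roi_001  1.972086  0.594678        False
2  roi_001  roi_005 -1.815363  0.594678        False
```

the two planted pairs rank first and second; with only 24 held-out
subjects one of them survives the FDR correction (the reference study
in `scripts/acceptance.py`, at n = 200 and N = 20, recovers all ten of
its planted pairs as the top ten edges).  The same workflow is
available from the shell:

```bash
pairconn simulate --out data/ --seed 7
pairconn train --data data/ --out run/ --head dx --preset desk
pairconn edges --data data/ --model run/split0 --out run/
```

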