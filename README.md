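# ignidyn

Intrinsic-ignition analysis of parcellated resting-state BOLD dynamics
across the Alzheimer's continuum.

Alzheimer's disease progressively degrades the brain's capacity to
integrate information across its large-scale functional network. This
package implements the intrinsic ignition framework for quantifying that
capacity from resting-state fMRI: each region's z-scored BOLD signal is
reduced to a point process of threshold crossings (*driving events*); for
every event, the regions co-activating within a short window form a binary
graph whose largest connected subcomponent, as a fraction of regions, is
the event's *integration*; the mean of a region's per-event integrations
is its **ignition** and their standard deviation its
**node-metastability** — the temporal variability of its network
engagement. On top of those per-region measures the package provides

- cohort comparisons: Monte-Carlo permutation tests with
  Benjamini–Hochberg FDR, Cohen's d, and a minimum-detectable-effect
  calculator;
- the cortical **hierarchy** (regions ranked by cohort-mean
  node-metastability) and the **Hierarchy Disruption Factor**
  HDF(a, b) = √Σ(a − b)² between two rank-aligned hierarchies;
- 7-network RSN label transfer to any parcellation by nearest-centroid
  matching;
- linear mixed-effects models linking regional node-metastability to
  amyloid-β and tau PET burden (`Meta ~ ABeta * Tau + (1 | subject)`, and an
  RSN-interaction variant with within-subject network random effects);
- disease-stage classification with mRMR feature selection and kNN under
  nested leave-one-out cross-validation, with permutation-importance
  feature attribution;
- a synthetic cohort generator with analytically known node-metastability
  and known mixed-model coefficients, so every stage is validated against
  ground truth (see `docs/methods.md`).

It is intended for computational neuroscientists working with parcellated
rs-fMRI (regions × time tables; any parcellation) and regional PET SUVR
tables.

## Worked example

Generate a severity-graded synthetic cohort (17 HC / 9 MCI / 10 AD
subjects, 100 regions), compute per-subject ignition profiles, and compare
the groups:

```python
import numpy as np
import ignidyn as ig
from ignidyn.ignition import ignition_profile
from ignidyn.stats import build_hierarchy, compare_groups, hdf

spec = ig.SyntheticSpec(n_regions=100, n_timepoints=1182, event_rate=0.3)
subjects, groups, _ = ig.generate_cohort(spec, seed=7)

profiles = {}
for sid, raster in subjects.items():
    prof, _ = ignition_profile(raster, window_trs=1)
    profiles[sid] = prof

values = {g: np.array([np.nanmean(p.node_metastability)
                       for s, p in profiles.items() if groups[s] == g])
          for g in ("HC", "MCI", "AD")}
print({g: round(float(v.mean()), 4) for g, v in values.items()})

report = compare_groups(values, n_perm=10_000, rng=7)
print(report[["group_a", "group_b", "observed_diff", "p_perm", "p_fdr", "cohen_d"]]
      .round(4).to_string(index=False))

hier = {g: build_hierarchy([p for s, p in profiles.items() if groups[s] == g])
        for g in values}
print("HDF(HC,MCI) =", round(hdf(hier["HC"], hier["MCI"]), 3),
      " HDF(HC,AD) =", round(hdf(hier["HC"], hier["AD"]), 3))
```

which prints

```
{'HC': 0.2015, 'MCI': 0.1904, 'AD': 0.1616}
group_a group_b  observed_diff  p_perm  p_fdr  cohen_d
     HC     MCI         0.0111  0.0006 0.0006   1.7559
     HC      AD         0.0399  0.0001 0.0001   6.4140
    MCI      AD         0.0288  0.0001 0.0001  10.5961
HDF(HC,MCI) = 0.111  HDF(HC,AD) = 0.399
```

Mean node-metastability declines monotonically from HC through MCI to AD
(the generator's severity parameter shrinks event-to-event recruitment
variability, which is exactly what node-metastability measures); all three
pairwise permutation tests survive FDR correction, and the hierarchy
disruption grows with clinical distance — the HC-vs-AD disruption is about
four times the HC-vs-MCI one.

The same analyses run from the shell on TSV inputs:

```
ignidyn simulate --out cohort/ --seed 7          # synthetic cohort + manifest
ignidyn run-all --manifest cohort/manifest.tsv \
    --labels cohort/labels.tsv --out run/        # full pipeline
```

`run/` then contains per-subject ignition profiles, per-cohort hierarchies
and pairwise disruption factors, permutation-test reports, mixed-model
coefficient tables, classification reports and a JSON log of every
parameter. Reruns with the same seed reproduce every file byte for byte.

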