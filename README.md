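# pediconn

Group analysis of weighted structural brain connectomes for
developmental cohorts.

`pediconn` implements the full statistical workflow used to compare
streamline-count connectomes between a clinical group and controls in
early childhood — the setting in which structural hyper-connectivity
and flattened network maturation have been reported in autism spectrum
disorder (ASD) relative to typically developing (TD) children.  It is
aimed at researchers who already have per-subject connectivity matrices
(e.g. 68 Desikan–Killiany cortical regions, edges weighted by the
number of reconstructed fiber streamlines) and want a tested, scriptable
implementation of the downstream network statistics, plus a synthetic
cohort generator for power analysis and method validation.

## What it computes

**Graph measures** (edge length `d_ij = 1/w_ij`, where `w_ij` is the
streamline count):

- network strength: mean nodal strength `S_i = Σ_j w_ij`
- global efficiency `Eg = (1/(N(N−1))) Σ_{i≠j} 1/L_ij`
- local efficiency `Eloc`: mean over nodes of `Eg` on each node's
  neighbour-induced subgraph
- characteristic path length `Lp`: mean finite shortest-path length
- nodal efficiency `E_nodal(i) = (1/(N−1)) Σ_{j≠i} 1/L_ij`
- hubs: nodes with `E_nodal ≥ mean + 1 SD`, identified on the
  group-average network at 15% sparsity

**Inference**:

- age-adjusted group comparison: GLM `y ~ intercept + group + age`,
  group coefficient reported as TD − ASD (negative t = higher in ASD)
- age-by-group interaction: `y ~ intercept + group + age + group×age`,
  with per-group fitted slopes
- Benjamini–Hochberg FDR applied separately within each hemisphere
- age-adjusted partial correlations of network measures with clinical
  severity scores (ABC, ADI-R, CARS, CABS), clinical group only
- network-based statistic (NBS): per-edge GLM t-map, suprathreshold
  connected components, and family-wise-error-corrected component
  p-values from a permutation null of the maximal component size
  (group labels shuffled, ages kept attached to subjects)

**Simulation**: a negative-binomial connectome generator with planted
group offsets, per-group log-scale age slopes, and clinical-score
couplings, each cohort carrying its ground truth for recovery testing.

## Worked example

```python
import numpy as np
from pediconn import (generate_cohort, preset_paper_like, global_efficiency,
                      group_difference_test, interaction_test,
                      pergroup_age_correlation)

cohort, truth = generate_cohort(preset_paper_like(seed=42))
eg = np.array([global_efficiency(cohort.connectomes[s.subject_id])
               for s in cohort.subjects])
gd = group_difference_test(eg, cohort.groups, cohort.ages)
ia = interaction_test(eg, cohort.groups, cohort.ages)
corr = pergroup_age_correlation(eg, cohort.ages, cohort.groups)
```

Running `python examples/02_group_inference.py` (the same computation)
prints:

```
global efficiency, group effect (age-adjusted): t = -4.073, df = 48, p = 0.0002
  (negative t: hyper-connectivity in the clinical group)
age-by-group interaction: t = +1.920, p = 0.0609
  fitted slopes: TD +6.760/y, ASD +3.130/y (flatter maturation in ASD)
r(age, Eg) in TD: +0.78 (p = 0.0000, n = 21)
r(age, Eg) in ASD: +0.42 (p = 0.0225, n = 30)
```

The negative group t says global efficiency is higher in the ASD group
after removing the age trend; the positive interaction slope gap and
the stronger TD age correlation show the planted "flattened
maturation" pattern.  The other scripts in `examples/` walk through
graph metrics and hubs, regional FDR inference with clinical
correlations, the NBS, and the end-to-end pipeline.

## Command line

```sh
pediconn simulate --out cohort --seed 42        # synthetic cohort directory
pediconn run-all cohort --out results --n-perm 10000 --seed 42
pediconn report results
```

`pediconn metrics`, `pediconn group-stats` and `pediconn nbs` run
single stages.  A cohort directory holds `subjects.tsv`, `nodes.tsv`
and one labelled matrix TSV per subject; all outputs are tidy TSV/JSON.

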