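# fdforest

Individual-based forest simulation and trait-diversity analysis of tree
survival under climate change.

Temperate forests face a century of warming, and a central open question in
forest ecology is what lets individual trees survive it: their own
functional traits, the state of the stand around them, or the functional
diversity of their neighbourhood. `fdforest` is a desk-scale laboratory for
that question. It couples

1. **a flexible-trait, individual-based forest gap model** — trees of four
   plant functional types (broad-leaved summergreen and evergreen,
   temperate and boreal needle-leaved) establish on independent
   10 m × 10 m patches with randomly drawn, lifetime-fixed traits on the
   leaf and stem economic spectra (specific leaf area SLA, leaf longevity,
   wood density WD); monthly light competition, phenology and carbon-stress
   mortality then filter which trait combinations persist — with
2. **a machine-learning survival analysis** — every tree standing at a
   reference year is tracked for a century, and a random-forest classifier
   predicts its survival from eight initial-state covariates: individual
   traits (SLA, WD, height), forest dynamics (number of competing trees
   > 5 m, local vegetation carbon), and patch functional diversity.

Functional diversity is measured per patch in the 3-D standardized trait
space (SLA, leaf longevity, WD) with three community indices:

- **functional richness** FR — the convex-hull volume of the patch's trait
  cloud (analysed as ln FR, which removes its strong right skew);
- **functional divergence** FDv = (Δd + d̄) / (Δ|d| + d̄) ∈ [0, 1], where
  d̄ is the mean distance of individuals to the gravity centre of the hull
  vertices and Δd, Δ|d| the weighted (absolute) mean deviations;
- **functional evenness** FE ∈ [0, 1], the regularity of weighted branch
  lengths EW<sub>l</sub> = dist<sub>l</sub>/(w<sub>i</sub>+w<sub>j</sub>)
  along the minimum spanning tree of the cloud.

The analysis yields (i) normalized permutation importances of the eight
covariates, aggregated into the three variable groups, whole-community and
split at 10 m height; and (ii) centred partial-dependence curves, from
which the headline statistic is assembled: the **additional survival
probability from functional diversity** — the summed partial-dependence
tail effects for high FR, high FDv and low FE (upper/lower 10% of the
initial distributions), with standard deviations propagated in quadrature.

## Worked example

```python
import fdforest as ff
from fdforest.importance import feasible_total

cfg = ff.SimulationConfig(n_patches=200, seed=42)
result = ff.run_simulation(cfg, scenario="warming")

t0 = result.trees_at(result.t0_year)      # scenario-start snapshot
t1 = result.trees_at(result.t1_year)      # scenario-end snapshot (100 y later)
indices = ff.snapshot_indices(t0)         # per-patch FR / FDv / FE

records = ff.label_survival(t0, t1, result.patches_at(result.t0_year),
                            indices, site="demo", scenario="warming")
records, _ = ff.drop_degenerate_records(records)
print(f"{len(records)} trees > 5 m at t0, "
      f"{records['survived'].mean():.1%} survived the century")

rf = ff.RFConfig(seed=0, subsample_total=feasible_total(records, 5000))
report = ff.run_importance_pipeline(records, rf)
print(f"test accuracy {report.accuracy:.2f}, AUC {report.auc:.2f}")
for group, share in report.groups.items():
    print(f"  {group:>22}: {share:.1%}")
```

prints

```
3023 trees > 5 m at t0, 17.5% survived the century
test accuracy 0.57, AUC 0.59
       individual_traits: 98.5%
         forest_dynamics: 0.0%
    functional_diversity: 1.5%
```

Read: over a warming century, survival of this simulated whole community is
dominated by each tree's own traits and size (environmental and competitive
filtering); diversity covariates matter little for the community as a
whole. Diversity effects concentrate in the understorey — the
mixed-vs-pure community experiment in `fdforest.planted` and the
stratified analysis (`stratified_importance`, `fd_effect_for_records`)
expose them there.

The same pipeline is available from the shell:

```bash
fdforest simulate --scenario warming --seed 1 --out run/
fdforest diversity --snapshot run/trees_0150.csv.gz --out div.csv
fdforest label --t0 run/trees_0150.csv.gz --t1 run/trees_0250.csv.gz \
               --patches run/patches_0150.csv.gz --diversity div.csv \
               --out records.csv
fdforest analyze --records records.csv --stratum both --out analysis/
fdforest effects --records records.csv --out effects/
fdforest report  --run run/ --out summaries/
```

## Layout

| Module | Contents |
| --- | --- |
| `fdforest.simulator` | PFTs, traits, climate, production/mortality/establishment kernels, the run loop |
| `fdforest.diversity` | trait standardization, FR / FDv / FE, per-patch index tables |
| `fdforest.cohort` | two-slice survival labelling, height stratification |
| `fdforest.importance` | balanced subsampling, train/test split, random forest, tuning grids, normalized permutation importance, variable groups |
| `fdforest.effects` | centred partial dependence, 10%-tail effects, quadrature error propagation, cross-site aggregation |
| `fdforest.planted` | logistic ground-truth cohorts and the mixed-vs-pure community experiment |
| `fdforest.report` | composition trajectories, trait distributions, height structure |
| `fdforest.cli`, `fdforest.plots` | command-line pipeline and figures |

See `docs/methods.md` for model equations, parameter choices and
limitations.
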