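# ndm

Network diffusion modelling of regional brain atrophy on weighted
structural connectomes.

Given a symmetric nonnegative connectivity matrix over a bilateral brain
parcellation and a regional atrophy map (t-statistics of volume loss),
the package simulates linear spread of pathology with the heat kernel of
the symmetric normalized graph Laplacian, `f(t) = exp(-alpha H t) f0`,
and scans every bilateral homologue pair as a candidate seed: each
seed's diffusion profile is correlated (Pearson, seed regions excluded)
with the measured atrophy across a model-time grid, and seeds are ranked
by their maximum correlation with family-wise correction across seeds.
Significance of the best correlation can be assessed against null
networks that preserve the weight multiset, binary degree sequence and
(approximately) the nodal strength distribution.

On the default 82-region bilateral Desikan-Killiany parcellation this
yields 41 seed conditions, a 41 x 51 correlation-time surface (unit time
steps 0..50) and 80-region correlations.

## Modules

| module | contents |
| --- | --- |
| `ndm.connectome` | connectome/region-table loading, validation, weighted degrees |
| `ndm.diffusion` | normalized Laplacian eigendecomposition, eigenmode propagation, independent `expm` oracle |
| `ndm.atrophy` | ICV normalization, two-sample / paired regional t-maps |
| `ndm.seed_scan` | repeated bilateral seeding, correlation traces, seed ranking, FWE correction |
| `ndm.null_models` | degree/weight/strength-preserving randomization, empirical null of max correlation |
| `ndm.synthetic` | synthetic bilateral connectomes and study data with a planted seed |

## Command line

```sh
# generate a synthetic study (connectome, volumes, atrophy, ground truth)
ndm simulate --seed 7 --out study/

# regional t-map from subject x region volume tables (ICV-normalized)
ndm atrophy --volumes study/volumes.tsv --design two-sample \
    --group-a patients --group-b controls --out study/tmap.tsv

# rank candidate seed regions against an atrophy map
ndm seed-scan --connectome study/connectome.txt --regions study/regions.tsv \
    --atrophy study/atrophy.tsv --tmax 50 --alpha 1 --correction bonferroni

# empirical null of the maximum seed-scan correlation
ndm null --connectome study/connectome.txt --regions study/regions.tsv \
    --atrophy study/atrophy.tsv -k 1000 --seed 0 --out study/null.tsv
```

Input formats: the connectome matrix is a headerless whitespace- or
comma-delimited square numeric table; the region table is a TSV with
columns `region_id  label  hemisphere  homologue_id`; volume tables are
subject x region TSVs with `subject_id`, `group` and `ICV` columns;
atrophy maps are TSVs with columns `region_label  t  p`.  Sign
convention: positive t means volume loss in the patient / later group.

## Python API sketch

```python
import ndm

spec = ndm.SyntheticSpec(rng_seed=0, seed_pair=11, t_star=12.0)
c = ndm.synth_connectome(spec)
atrophy, truth = ndm.synth_atrophy(spec, c)

result = ndm.repeated_seed_scan(c, atrophy)
print(result.top_seed(), truth["seed_label"])

null = ndm.null_distribution(c, atrophy, k=200, rng_seed=1)
print(null.observed_max_r, null.percentile_95, null.empirical_p)
```
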