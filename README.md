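# gradient-niche

Statistical analysis of species communities sampled along land-use
gradients: community-weighted trait means, abundance-weighted environmental
niches, permutation tests for land-use winners and losers, niche
hypervolumes, and Red-List vulnerability models.  The package was built
around land-snail communities surveyed on standardized forest and grassland
plots in three regions (with gradients such as the compound land-use
intensity index LUI, mowing/grazing/fertilization, the forest management
index FORMI and its single components, soil pH and soil moisture), but every
routine works on any site × species count matrix with a matching
site-environment table.

## What it computes

**Community-weighted mean (CWM).**  For a trait with species values `T_i`
and counts `a_ip` in plot `p` (plot total `A_p`):

    CWM_p = Σ_i T_i · a_ip / A_p

CWMs are modelled per gradient with sequential (type-I) ANOVA of
`CWM ~ gradient + region + gradient:region`, and compared between habitats
(per-region ANOVA) and regions (Tukey HSD).

**Environmental niche.**  Each species' niche optimum on a gradient `L_p` is
the abundance-weighted mean, its niche breadth the abundance-weighted
standard deviation, with `A_i` the species total:

    AWM_i  = Σ_p L_p · a_ip / A_i
    AWSD_i = sqrt( Σ_p a_ip (L_p − AWM_i)² / A_i )
    CV_i   = AWSD_i / AWM_i

**Null model and classification.**  Observed values are tested against a
permutation null that redistributes the species' observed abundances over
`N_i` sites drawn without replacement from the plots of the habitat,
restricted to the regions where the species was recorded (10,000 iterations
by default).  A species is a *winner* if its observed AWM exceeds the null
95th percentile, a *loser* below the 5th; otherwise it is a
*mid-specialist* when its CV is narrower than the null 5th percentile (and
nonzero), else *neutral*.  For abiotic gradients (pH, moisture) the labels
are *high*/*low*.

**Hypervolume and vulnerability.**  The five-dimensional niche hypervolume
is the product of the AWSDs of the three single land-use components plus pH
and moisture, per habitat.  Vulnerability (the Red-List code as an ordinal
rank) is modelled by a Poisson GLM on the focal gradient's AWM, log
occurrence and log total abundance, and correlated with the hypervolume by
a Spearman rank test reported through the S statistic.

A synthetic-community generator (`ScenarioConfig`, `generate_dataset`)
produces datasets with Gaussian species response curves and known ground
truth (true optima, breadths, habitat affinities, declared statuses), so
every estimator is testable end to end.  The species status tables printed
for the original snail survey ship with the package
(`gradient_niche.published`).

## Worked example

```python
import gradient_niche as gn

config = gn.ScenarioConfig(seed=42, n_species=12)
env, abund, traits, redlist, truth = gn.generate_dataset(config)

grass_env = env.subset(habitat="grassland")
grass_ab = abund.subset_plots(grass_env.plots).drop_empty_species()

table = gn.species_response_table(
    grass_ab, grass_env, ["LUI", "pH"], redlist=redlist,
    n_iter=10_000, seed=42,
)
print(table[["redlist", "regions", "occurrence", "abundance", "LUI", "pH"]])
```

```
        redlist regions  occurrence  abundance             LUI              pH
species
sp001         *     AHS          58        489           loser         neutral
sp005         V     AHS          57        407  mid-specialist         neutral
sp006         3     AHS         150       1311         neutral  mid-specialist
sp007         G     AHS         150       2169         neutral             low
sp011         *     AHS         150       2185         neutral             low
```

`sp001` was generated with its optimum at the LUI minimum and is correctly
called a loser of land-use intensity (its observed niche optimum,
`AWM = 0.951`, sits far below what random placement over its 150-plot
regional pool would give); `sp005` was built as a narrow intermediate-LUI
specialist and is recovered as a mid-specialist; the flat-response species
are neutral.  The same machinery runs end to end from a config file:

```bash
gradient-niche run --config cfg.yaml     # validate → CWM → niche → hypervolume → vulnerability
gradient-niche synth --seed 4 --out data/
gradient-niche classify --env data/environment.csv --abundance data/abundance.csv \
    --habitat grassland --seed 4 --out status.csv
```

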