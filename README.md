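# richabund

Causal direction of the species richness–tree abundance relationship in
forest communities, estimated region by region with piecewise structural
equation models (SEMs).

## The problem

Plots with more tree species often hold more trees. Two causal readings
compete:

* **More species hypothesis (MSH)** — richness drives abundance
  (complementarity and facilitation let more stems coexist): `S → A`.
* **More individuals hypothesis (MIH)** — available energy drives
  abundance, and abundance determines how many species persist: `A → S`.

Within a forest region, each inventory plot contributes its species
richness `S`, tree abundance `A`, mean tree size `D` (mean DBH, cm) and
elevation `E`. Both candidate models share the elevation gradients
`E → ln S`, `E → D`, `E → ln A` and the self-thinning (Yoda's law) path
`D → ln A`; they differ only in the direction of the richness–abundance
link. A third, NULL candidate omits the link entirely.

Each candidate is a piecewise SEM: a set of local regressions over the DAG,
judged as a whole through its d-separation basis set and Fisher's C,

```
C = -2 Σ ln p_i        ~  χ²(2k)  under the hypothesized graph,
BIC = C + K ln n       CIC = C + 2K
```

where the `p_i` are the basis-set claim p-values, `K` the total parameter
count and `n` the number of plots. The signed difference

```
ΔBIC = BIC_MSH − BIC_MIH
```

classifies the region: `ΔBIC < −2` supports MSH, `ΔBIC > +2` supports MIH,
and values in between count as equivalent support. When even the better
directional model has a larger BIC than the NULL candidate, the
richness–abundance link is considered weak in that region.

At the global level, one record per region (its ΔBIC, Miami-model
climatological NPP, absolute latitude, mean richness and plot size) feeds a
five-node SEM testing whether productivity controls which causal direction
prevails, with latitude allowed to act only through climate and richness.

Because the original inventories are largely restricted, the package ships
(a) the published per-region BIC table as a fixture, so all classification
arithmetic is reproducible exactly, and (b) a synthetic-data generator that
emulates plot-level inventories under a chosen causal regime, so every
model-fitting stage is testable end to end.

## Worked example

```python
from richabund import RegionScenario, simulate_region, run_region

region = simulate_region(RegionScenario(regime="MSH", n_plots=500, seed=3))
result = run_region(region)
print(result.classification, round(result.delta_bic, 2), result.null_flag)
```

prints

```
MSH -21.32 False
```

ΔBIC = −21.3 is far below the −2 threshold, so the richness→abundance
model is decisively preferred on this synthetic region (as it should be:
the data were generated under the MSH regime with a standardized cross-path
strength of 0.6), and the directional model also clearly beats the null
(`null_flag=False`).

The same pipeline is exposed on the command line:

```
richabund simulate --regime MSH --n-plots 500 --seed 3 --out region.csv
richabund classify-all --plots region.csv --out table.csv
richabund classify-all --fixture --out table1.csv   # published BIC table
richabund meta --regions meta.csv --out meta.json
richabund npp --climate climate.csv --out npp.csv
```

`classify-all --fixture` reports
`{"msh": 8, "mih": 6, "equivalent": 9, "null_flag": 3, "misfit_flag": 2}`:
of the 23 published forest regions, the diversity effect prevails in 8, the
abundance effect in 6, support is equivalent in 9, and in 3 regions the
null model beats both directional models.

The numbered drivers under `analysis/` run the full narrative — published
table classification, the simulated per-region pipeline, and the
cross-region productivity SEM — writing their tables under `results/`.

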