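# lhspectra

Functional spectra of life-history strategies — and how extinctions of
threatened species erode them.

Long-lived reptiles such as turtles, tortoises, and crocodilians pack
their demography into a handful of life-history traits: adult and
juvenile survival (*Sa*, *Sj*), maximum lifespan (*ML*), age at sexual
maturity (*Lα*), clutches per year (*CN*), and clutch size (*CS*).
`lhspectra` turns a species-level phylogeny, a gappy trait table, and
IUCN-style threat metadata into a quantitative picture of the clade's
functional diversity and its vulnerability:

1. **Phylogenetic imputation** — missing traits are filled by
   chained-equations predictive mean matching with phylogenetic
   eigenvector covariates, repeated 40 times to carry imputation
   uncertainty (`impute`).
2. **Phylogenetic PCA** — traits are log/logit-transformed, corrected
   for body mass by PGLS residuals, and decomposed by a pPCA that
   estimates Pagel's λ jointly; PC1 is the fast–slow continuum, PC2 the
   reproductive-strategy (clutch frequency vs clutch size) axis
   (`phylo`, `ppca`).
3. **Trait probability density** — species become Gaussian kernels in
   the 2-D functional space (plug-in bandwidth **H**); the summed,
   normalised density on a 200×200 grid, thresholded to its 99%
   highest-density region, measures occupied functional space (`tpd`).
4. **Extinction scenarios** — species are removed cumulatively by IUCN
   category (−CR, −EN, −VU, −NT) or by threat flag, and the percentage
   of occupied cells that empty is compared with a 999-iteration
   random-removal null envelope (`scenarios`).
5. **Risk surfaces** — binomial tensor-spline GAMs map the probability
   of being high-risk (or threat-affected) across the functional space
   (`surface`).

A synthetic-data generator (`synthetic`) produces phylogenies, trait
tables, gaps, and status/threat labels with the statistical structure
the analysis assumes, so the whole pipeline is testable end to end
without external data.

## Worked example

Run the full pipeline on a synthetic 120-species clade (10 imputations,
199 null iterations, 100×100 grid to keep it quick):

```python
import lhspectra as lh
import pandas as pd, yaml

cfg = lh.RunConfig(
    sim=lh.SimConfig(n_species=120, seed=42),
    n_imputations=10, n_null_iter=199, cells_per_dim=100,
    seed=42, out_dir="readme_run",
)
run = lh.run_pipeline(cfg)

ppca = yaml.safe_load(open(run / "ppca.yaml"))
tpd = yaml.safe_load(open(run / "tpd.yaml"))
print(f"pooled Pagel's lambda : {ppca['lambda_hat']:.3f}")
print(f"PC1 / PC2 variance    : {100*ppca['var_explained'][0]:.1f}% / "
      f"{100*ppca['var_explained'][1]:.1f}%")
print(f"hotspot (50% HDR)     : {100*tpd['hotspot_species_fraction']:.0f}% "
      f"of species in {100*tpd['hotspot_area_fraction']:.1f}% of the spectrum")
scen = pd.read_csv(run / "scenarios.csv")
iucn = scen[scen.scenario.isin(["-CR", "-EN", "-VU", "-NT"])]
print(iucn[["scenario", "n_removed", "loss_pct", "null_p5", "null_p50",
            "null_p95", "exceeds_null"]]
      .to_string(index=False, float_format=lambda v: f"{v:.2f}"))
```

which prints:

```
pooled Pagel's lambda : 0.746
PC1 / PC2 variance    : 32.5% / 24.3%
hotspot (50% HDR)     : 62% of species in 21.7% of the spectrum
scenario  n_removed  loss_pct  null_p5  null_p50  null_p95  exceeds_null
     -CR          8      0.02     0.00      0.72      5.71         False
     -EN         22      0.48     0.31      2.23      9.13         False
     -NT         48      3.82     1.67      5.91     12.78         False
     -VU         39      1.78     1.37      5.62     12.05         False
```

Reading the output: the six traits compress onto two dominant axes
(~57% of variance) with strong phylogenetic signal (λ ≈ 0.75 — trait
similarity tracks the tree).  Species crowd into a hotspot: 62% of them
occupy ~22% of the occupied spectrum, i.e. high functional redundancy.
In this synthetic world, risk is only weakly tied to trait position, so
each scenario's loss falls inside its random-removal envelope
(`exceeds_null` False); with risk concentrated on peripheral strategies
the observed loss instead exceeds the 95th null percentile.

The same pipeline runs on real files:

```sh
lhspectra all --tree tree.nwk --traits traits.csv --meta meta.csv \
    --seed 1 --out run/
```

with trait CSVs using empty cells for missing values and metadata
columns `iucn`, the six threat flags, and `continent`.  Every run
directory contains the imputed datasets, pooled pPCA scores/loadings,
TPD summaries, the scenario table, risk-surface grids, and a manifest
with all seeds — rerunning the same config reproduces every artifact
bit-identically.

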