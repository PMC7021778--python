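# divsignal

**Do community-level diversity responses carry phylogenetic signal?**

When many taxonomic families share one environmental gradient, each family's
local assemblages respond in their own way: species richness may rise, fall,
or peak at some elevation, and species composition turns over at different
rates with geographic distance, elevational distance or habitat change.
`divsignal` asks whether those *community-level* response parameters behave
like heritable lineage traits — whether closely related families respond more
similarly than distant ones — and provides every statistical step needed to
answer it from presence–absence survey data:

1. **Community data handling** — binary site × species matrices with a
   species → family taxonomy; families are retained when they occupy ≥ 50
   plots and contain ≥ 5 species (both configurable).
2. **α-diversity responses** per family, on its presence-only sites:
   * *Edf-α*: effective degrees of freedom of a penalized cubic-spline smooth
     of ln(richness) on elevation (GCV-selected smoothing). Edf ≈ 1 means a
     linear cline; Edf ≈ 5 has the complexity of a degree-4 polynomial.
   * *Peak-α*: the elevation where richness peaks, estimated as the breakpoint
     ψ of a two-segment regression of ln(richness) on elevation, with SE
     derived from the 95% profile-F confidence interval.
3. **β-diversity responses**: pairwise Sørensen dissimilarity
   (b+c)/(2a+b+c) regressed on geographic, elevational and habitat
   (arcsine-√cover Euclidean) distances by multiple regression on distance
   matrices (MRM) with 999-permutation inference — giving *Slope_xy*,
   *Slope_z*, *Slope_hab* (joint model) and *R²_xy*, *R²_z*, *R²_hab*
   (single-predictor models, zeroed when non-significant).
4. **Phylogenetic signal** of each response across families:
   * Blomberg's **K** (expectation 1 under Brownian motion, 0 under
     independence), with optional measurement-error weighting via the SEs;
   * regressions of pairwise response dissimilarities (Cohen's *d* or raw
     differences) on **patristic distances** (twice the divergence-node age);
   * Fritz–Purvis **D** for the binary widespread-vs-rare contrast;
   * the **C-score** co-existence matrix regressed on patristic distance.
5. **WN vs BM model comparison** with Monte-Carlo power: fit white-noise
   (iid normal) and Brownian-motion (covariance σ²C) models by ML, simulate
   1000 datasets from each fit, refit both models everywhere, and compare the
   observed likelihood-ratio statistic δ = 2(lnL_BM − lnL_WN) with its
   simulated null.
6. **Phylogenetic GLS** of responses on family traits with residual
   covariance σ²·W^{1/2}VW^{1/2} (V = BM correlation, W = variance weights),
   ranked by AICc with Akaike weights (ΔAICc < 3 = equal support).
7. A **synthetic-data generator** producing full studies (ultrametric Yule
   tree, BM-evolved response parameters, landscape, occurrence matrices) with
   recorded ground truth, so every stage is testable end to end.

## Worked example

Simulate a study of 12 families surveyed at 300 sites, then run the full
analysis:

```bash
divsignal simulate --n-families 12 --n-sites 300 --seed 4 --out demo
divsignal all --matrix demo/occurrence.csv --taxonomy demo/taxonomy.csv \
    --metadata demo/sites.csv --tree demo/tree.nwk --out demo_results \
    --min-plots 30 --n-perm-mrm 199 --n-perm-signal 199 --n-sim-pmc 200 --seed 11
```

`demo_results/` then contains `responses.csv` (the eight response variables
per family), `signal.csv`, `cscore.csv` and a machine-readable
`results.json`. With the commands above the signal table includes, e.g.:

```
peak     K=0.732  K_p=0.095  dist_p=0.765   (Cohen's d vs patristic distance)
slope_z  K=0.089  K_p=0.770  dist_p=0.870
```

and the Monte-Carlo model comparison for *Peak-α* reports
`delta_obs=-2.073, power=0.47, preferred_model=WN`. Reading this: although
the generator evolved the true peaks under Brownian motion, at 12 families
the permutation test does not reach significance and the power of the WN/BM
comparison is below 0.5 — exactly the small-sample behavior the Monte-Carlo
power analysis is designed to expose. Recovering the *ranking* of turnover
rates, or calibrating K on hundreds of replicates (below), is where the
machinery is demonstrably accurate.

The same stages are available as a library:

```python
from divsignal import synthetic, signal
tree = synthetic.simulate_tree(20, depth_ma=300.0, seed=42)
traits = synthetic.simulate_bm_traits(tree, sigma2=1.0, n_reps=1, seed=1)
res = signal.blomberg_k(traits.iloc[0].to_dict(), tree, n_perm=999, seed=0)
print(res.k, res.p)
```

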