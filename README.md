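# lowbiom

Density-aware contaminant identification and filtering for low-biomass
16S rRNA amplicon data.

## The problem

Airway samples such as bronchoalveolar lavage fluid (BALF) often carry
very little bacterial DNA — anywhere from ~10³ to ~10¹⁰ 16S copies/ml.
Reagents and handling introduce a roughly *constant* absolute load of
contaminating DNA into every extraction, so the lower a sample's own
density, the larger the share of its reads that come from contaminants.
Below a density crossover the sequenced profile is mostly reagent
background, and relative-abundance results become misleading unless the
contaminants are identified and removed.

`lowbiom` implements a contaminant model built on two fingerprints that
distinguish reagent background from genuine community members, plus the
evaluation framework needed to quantify what filtering buys you:

* **Feature 1** — for OTU *i* with relative abundance *aᵢⱼ* in sample
  *j* and measured sample input density *Dⱼ* (16S copies/ml by qPCR),
  the Spearman rank correlation ρᵢ = corr(rank *aᵢ·*, rank *D·*).
  Contaminants have ρᵢ < 0 (constant load over a shrinking total);
  an OTU is flagged when ρᵢ < 0 and the two-sided p-value
  (t-approximation on n−2 df) is ≤ α (default 0.05).
* **Feature 2** — an OTU present in exactly one member of a
  technical-replicate group (a *singleton*): low-copy contaminants drop
  in and out stochastically between parallel extractions.
* **Filters** — `F1` removes Feature-1 OTUs everywhere; `F2` zeroes an
  OTU only inside replicate groups where it is a singleton; `F3`
  applies F1, then re-derives and applies F2 on the filtered table.
* **Evaluation** — *accuracy* is the Bray-Curtis dissimilarity
  BC(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) between the observed profile
  (aggregated to the expected taxa plus one pooled contaminant bin) and
  a known mock composition; *precision* is the BC between technical
  replicates.  Wilcoxon signed-rank and Mann-Whitney U tests compare
  treatment arms.
* **Simulation** — a seeded generator reproduces the study design
  (three mock communities, a tenfold dilution ladder 8E+02–8E+09
  copies/ml, lognormal density-independent background, replicate pairs,
  no-template controls, optional tenfold concentration, fixed-depth
  multinomial sequencing) with ground-truth labels, so every claim the
  package makes is testable without external data.

It also includes qPCR plumbing (standard-curve fitting and the
copies/ml volume algebra) to attach densities to sample metadata.

## Worked example

```python
import lowbiom as lb

data = lb.simulate_dataset(seed=1)          # 608 OTUs x 56 samples
result = lb.ContaminantModel(data.table, data.metadata).fit()
print(result.summary())

filtered, report = result.apply_filter("F3")
before = lb.accuracy(data.table, data.taxonomy, data.expected, data.metadata)
after = lb.accuracy(filtered, data.taxonomy, data.expected, data.metadata)
for density in sorted(before["density"].unique()):
    b = before.loc[before.density == density, "accuracy_bci"].median()
    a = after.loc[after.density == density, "accuracy_bci"].median()
    print(f"{density:9.0e} copies/ml   BCI {b:.3f} -> {a:.3f}")
```

prints

```
Contaminant feature model
============================================================
OTUs: 608    samples: 56
alpha: 0.05   multiple testing: none   min prevalence: 0.0
presence threshold: 1 (reads)
------------------------------------------------------------
Feature 1 (density-anticorrelated): 568 OTUs (51.8% of reads)
Feature 2 (replicate singletons):   589 OTUs
both features:                      556 OTUs
labelled contaminant:               601 / 608 OTUs
============================================================
    8e+02 copies/ml   BCI 0.999 -> 0.093
    8e+03 copies/ml   BCI 0.990 -> 0.039
    8e+04 copies/ml   BCI 0.912 -> 0.011
    8e+05 copies/ml   BCI 0.498 -> 0.004
    8e+06 copies/ml   BCI 0.094 -> 0.004
    8e+07 copies/ml   BCI 0.010 -> 0.004
    8e+08 copies/ml   BCI 0.005 -> 0.005
    8e+09 copies/ml   BCI 0.003 -> 0.003
```

Reading this: at 8E+05 copies/ml the unfiltered profile is already half
contaminant reads (median dissimilarity to the known composition 0.50);
below that, contaminants dominate almost completely.  Combined filtering
(F3) restores near-perfect compositional accuracy down to ~8E+03
copies/ml, while high-density samples — which contain almost no
contaminant reads to begin with — are left essentially untouched.

The same workflow is available from the shell:

```sh
lowbiom simulate --seed 1 --out-dir sim/
lowbiom flag     --table sim/otu_table.tsv --metadata sim/metadata.tsv --out calls.tsv
lowbiom filter   --table sim/otu_table.tsv --metadata sim/metadata.tsv \
                 --mode F3 --out filtered.tsv --report removals.tsv
lowbiom evaluate --table filtered.tsv --metadata sim/metadata.tsv \
                 --taxonomy sim/taxonomy.tsv --expected sim/expected.tsv \
                 --mode accuracy --out accuracy.tsv
lowbiom quantify --standards std.tsv --ct ct.tsv --out densities.tsv
```

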