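# amplicore

Community analysis of 16S amplicon **shared OTU tables**, built around a
reproducible delineation of the **core microbiome** — the set of OTUs present
in every sample, abundant enough to be trusted, and *evenly distributed*
across samples.

## Who this is for

Microbial ecologists working with samples × OTUs read-count tables (the mothur
`.shared` convention) from small multi-sample surveys — e.g. a handful of soil
samples along a heavy-metal contamination gradient — who want the downstream
statistics done carefully at small *n*: even-depth normalization, richness and
diversity estimation with honest confidence intervals, community overlap, rank
correlation with environmental variables, and a principled core-microbiome
call.

## The core statistic

Membership of the core microbiome is decided per OTU from its vector of
per-sample read counts (n₁, …, n_S). Three criteria apply simultaneously:

1. **read floor** — nⱼ ≥ 3 in *every* sample j ("more than two reads", so
   cross-sample presence is unlikely to be sequencing noise or barcode
   bleed-through);
2. **frequency floor** — nⱼ/Nⱼ > 0.1 % of sample j's reads, in every sample;
3. **evenness** — the cross-sample Shannon evenness

   E = (−Σⱼ pⱼ ln pⱼ) / ln S,  pⱼ = nⱼ / Σⱼ nⱼ,

   treating the *samples* as categories and the OTU's reads as individuals,
   must exceed 0.9. E = 1 means the OTU's reads are spread equally over all S
   samples; E → 0 means they concentrate in one.

All thresholds are configurable (`CoreCriteria`). The read floor and the
frequency floor are deliberately independent filters: at an even depth of
1,500 reads, 0.1 % is 1.5 reads, so the two conditions are *not* equivalent
and both are enforced.

Around this sit the standard pipeline stages: without-replacement
(multivariate hypergeometric) down-sampling to even depth with
replicate-averaged tables; Chao1 (bias-corrected), ACE, Shannon H′/evenness,
Faith's rooted PD and analytic rarefaction; Bray-Curtis, Morisita-Horn and
Sørensen dissimilarities; Venn (shared-OTU) accounting; and Spearman
correlation with **exact permutation p-values** for n ≤ 8.

## Worked example

Simulate a five-sample survey with a planted 20-OTU core and a contamination
gradient, normalize to even depth, and delineate the core:

```python
import amplicore as a

ds = a.simulate(a.SimulationConfig(seed=7))          # synthetic survey + truth
depth = int(ds.table.sample_totals().min())
avg = a.averaged_shared(ds.table, a.SubsampleSpec(depth, replicates=5, seed=7))
report = a.CoreMicrobiome(avg, ds.taxonomy).fit(a.CoreCriteria())
print(report.summary())
```

prints (truncated):

```
Core microbiome delineation (label 0.03)
  samples: S1, S2, S3, S4, S5
  criteria: count >= 3 in every sample; frequency > 0.10% in every sample; cross-sample evenness > 0.9
  note: thresholds applied to subsample-averaged (fractional) counts
  core OTUs: 20 of 424 (4 near-misses)

           S1    S2    S3    S4    S5  evenness  total                                          taxonomy
Otu0019  10.0  17.6  14.6  17.2  18.6     0.987   78.0  D1;P1_1;C1_1_2;O1_1_2_4;F1_1_2_4_1;G1_1_2_4_1_5;
Otu0020  15.0  11.6  22.6  11.4  11.8     0.975   72.4  D1;P1_3;C1_3_2;O1_3_2_3;F1_3_2_3_1;G1_3_2_3_1_5;
...
```

Each row is a core OTU: its per-sample mean counts after five-fold
down-sampling to 2,632 reads, its cross-sample evenness E, its total, and its
lineage. Here all 20 planted core OTUs are recovered with no false positives,
and the contamination gradient is detected at full strength:

```python
sobs = (a.downsample(ds.table, depth, seed=7).to_numpy() > 0).sum(axis=1)
print(a.spearman(ds.env.data["metal"].to_numpy(), sobs.astype(float)))
# Spearman(x, y): rho=-1.000, p=0.01667 (n=5, exact-permutation)
```

Note the exact two-sided permutation p-value: with n = 5, a perfect monotone
association can never be "p = 0"; the smallest attainable p is 2/120 ≈ 0.017.

The same stages are scriptable from the shell (`amplicore subsample|alpha|
dist|venn|core|correlate|simulate|pipeline run`); `amplicore pipeline run
--config run.yaml` executes the whole chain and stamps every output with the
config hash and seed.

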