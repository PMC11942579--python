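# ginqc

Quality-consistency evaluation of herbal batches from genetic marker profiles
and chromatographic fingerprints.

Batch-to-batch consistency is a central problem in the quality control of
herbal materials such as ginseng (*Panax ginseng*): chemical fingerprints can
only be measured after production, while much of the chemical fluctuation
within a batch traces back to genetic heterogeneity of the raw material.
`ginqc` implements a pipeline that quantifies both kinds of within-batch
heterogeneity on a common information-entropy scale, converts the fluctuation
into the size of a Hardy–Weinberg equilibrium population (HWEP), derives the
minimum quantity for one sampling (MQS) per batch, and correlates genetic
with chemical heterogeneity across batches. It is aimed at analysts working
with dominant markers (ISSR/RAPD band matrices) and pharmacopoeia-style
UPLC/HPLC fingerprints.

## The model

For a sample amplifying `m2` of the panel's `m1` scored bands, the
band-profile information entropy is

```
H = -C · ln(m2 / m1),        C = 1/ln 2  (H in bits)
```

For a chromatographic fingerprint with common-peak areas `a_i`
(`f_i = a_i / Σa`), the fingerprint entropy is

```
Sp = -Σ_i a_i · ln(f_i)      (response units × nats, Sp ≥ 0)
```

Within a batch, the relative standard deviation `RSD = s/x̄` of the per-sample
entropies measures heterogeneity, and the HWEP size is

```
n = 100 · (t_{α,n−1} + u_β)² · RSD²  = 100 · 10.8² · RSD²    (α = β = 0.05)
```

with `MQS = n × (unit mass)` in kg (1.000 g equilibrium units by default).
Around this core the package provides per-primer polymorphism statistics
(TNB/NPB/PPB), Dice/Jaccard/simple-matching similarity with UPGMA dendrograms
(Newick export), cosine fingerprint similarity against a mean reference
chromatogram, leave-one-primer-out and leave-one-peak-out cross-validation of
n and MQS, exact small-sample Spearman correlation, and seeded synthetic-data
generators for band matrices and peak tables.

## Worked example

Recompute the per-batch genetic HWEP report from the bundled reference
ginseng study (five decoction-piece batches PG01–PG05, garden ginseng GG,
forest-grown ginseng FG; three samples each on a 92-band, 8-primer ISSR
panel), then correlate it with the chemical report from the six-common-peak
fingerprint panel:

```python
import ginqc

ref = ginqc.load_reference_tables()
entropies = {
    batch: [ginqc.band_entropy(int(m2), ref.panel_total_bands) for m2 in grp["m2"]]
    for batch, grp in ref.band_counts.groupby("batch_id", sort=False)
}
report = ginqc.batch_hwep_report(entropies)
print(ginqc.entropy_hwep.write_report(report))

chem = ginqc.batch_hwep_report(ref.entropy_groups("6peak"))
print(ginqc.spearman_exact(report["n"], chem.loc[report.index, "n"]))
```

Output:

```
          n_samples  mean_entropy  RSD_percent       n  MQS_kg
batch_id
PG01              3        0.3807         6.16   44.30   0.044
PG02              3        1.4098         6.07   43.02   0.043
PG03              3        1.0347        10.99  141.00   0.141
PG04              3        1.2638         4.52   23.86   0.024
PG05              3        1.2288         9.25   99.80   0.100
GG                3        0.1778         5.75   38.53   0.039
FG                3        0.8814         9.83  112.79   0.113
CorrelationResult(rho=0.8571428571428572, p_value=0.023809523809523808, n_pairs=7, method='exact_permutation')
```

Reading: the genetically tightest batches (PG04, GG) need the smallest
sampling quantities (≈ 0.02–0.04 kg), the most heterogeneous ones (PG03, FG)
the largest (0.141 and 0.113 kg), and the ranking of genetic HWEP sizes
agrees with the ranking of chemical HWEP sizes across the seven batches
(Spearman ρ = 0.857, exact permutation p = 0.024) — genetic heterogeneity
largely predicts chemical fluctuation.

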