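# rnadeg

Structure-aware prediction, aggregation, evaluation and curation of RNA
in-line hydrolysis measurements.

RNA backbones cleave spontaneously through in-line attack of the 2′-OH on the
adjacent phosphodiester — the chemistry that limits the shelf life of mRNA
vaccines. High-throughput probing assays measure this per nucleotide on short
RNA constructs under accelerated degradation conditions (high pH, Mg²⁺,
heat), alongside SHAPE reactivity. `rnadeg` is a toolkit for working with
such data: it parses secondary structures and annotates loop types, fits
windowed sequence+structure models of per-nucleotide degradation, aggregates
per-nucleotide rates into whole-molecule half-lives, scores predictions with
the multi-channel metrics used for blind evaluation, curates datasets
(quality filtering and cluster-based blind-test splits), combines prediction
sets by averaging or genetic-algorithm selection, and generates synthetic
datasets with planted signal so the entire pipeline is testable offline.

## The models and metrics

**Windowed linear degradation model** (the DegScore family). The degradation
score of nucleotide *i* is a linear function of the one-hot sequence and
loop-type context in a window of half-width *w*:

```
Y_i = Σ_{k=-w..w} Σ_{n ∈ {A,C,G,U}}     β_{k,n} · I(seq[i+k] = n)
    + Σ_{k=-w..w} Σ_{s ∈ {H,E,I,M,B,S}} β_{k,s} · I(loop[i+k] = s)
    + β₀
```

with (2w+1)·10 + 1 free parameters (251 at the standard w = 12). Loop types
follow the bpRNA nomenclature (S stem, H hairpin, I internal loop, B bulge,
M multiloop, X external loop, E end), with X folded into E for modelling. A
gradient-boosted variant trains XGBoost on the same indicator columns.

**Whole-molecule stability.** The overall degradation rate of an mRNA is the
sum over its linkages, `k_mRNA = Σ_i k_i`, and its half-life is
`t½ = ln 2 / k_mRNA`. Predictions are computed over the full sequence and
summed over the probed window (e.g. 5′UTR+CDS), so UTR–CDS base pairing is
reflected.

**Evaluation.** Predictions over multiple measurement channels are scored
with the mean column RMSE,
`MCRMSE = (1/N_t) Σ_j sqrt((1/n) Σ_i (y_ij − ŷ_ij)²)`, pooling scored
positions across constructs within each channel. Per-construct data quality
is the signal-to-noise ratio `SN = (1/M) Σ_i (1/N) Σ_j μ_ij/σ_ij`. The
within-error fraction counts positions where a prediction lies strictly
inside the measurement's error bar; for Gaussian errors a perfect predictor
reaches erf(1/√2) ≈ 68.3%.

**Curation.** Records pass the quality filter when all degradation values lie
strictly in (0.5, 20) and the SHAPE signal-to-noise exceeds 1; failing
records are kept and flagged `SN_filter = 0`. For blind-test curation,
sequences are clustered agglomeratively on normalized edit distance and cut
at a cophenetic height of 0.5; every member of a cluster of size ≤ 3 goes to
the private test set.

## Worked example

```python
from rnadeg import (SyntheticConfig, make_dataset, DegradationWindowModel,
                    score_predictions)

cfg = SyntheticConfig(n_constructs=120, seed=7, fail_fraction=0.1)
records = make_dataset(cfg)
kept = [r for r in records if r.SN_filter == 1]
print(f"{len(kept)} of {len(records)} constructs pass the quality filter")

train, test = kept[:90], kept[90:]
res = DegradationWindowModel(train, "deg_Mg_pH10").fit(ridge_lambda=0.1)
print(res.summary())

pred = res.predict_records(test)
report = score_predictions(test, pred, channels=["deg_Mg_pH10"])
print(f"held-out RMSE: {report.per_channel_rmse['deg_Mg_pH10']:.4f}")
print(f"within-error fraction: {report.within_error_fraction['deg_Mg_pH10']:.3f}")
```

prints

```
108 of 120 constructs pass the quality filter
Windowed linear degradation model
============================================
channel:            deg_Mg_pH10
window half-width:  12  (251 parameters)
ridge lambda:       0.1
n scored positions: 6120
design rank:        213 / 251
training RMSE:      0.32796
intercept:          3.05527
...
held-out RMSE: 0.3530
within-error fraction: 0.638
```

The synthetic data carry planted linear signal plus heteroscedastic noise
with standard deviation ≈ 0.33 at the typical signal level, so a held-out
RMSE of 0.353 means the fit has recovered nearly all recoverable signal; the
within-error fraction of 0.638 approaches the 0.683 ceiling of a perfect
predictor under Gaussian noise. The one-hot design is exactly collinear
(rank 213 of 251 columns here), which the ridge penalty resolves.

The same pipeline is scriptable from the shell:

```
rnadeg simulate --n 120 --seed 7 --out data.jsonl
rnadeg filter --records data.jsonl --out flagged.jsonl
rnadeg train --records flagged.jsonl --channel deg_Mg_pH10 --model-out model.json
rnadeg predict --model model.json --records flagged.jsonl --out pred.csv
rnadeg score --truth flagged.jsonl --pred pred.csv --channels deg_Mg_pH10
```

plus `split`, `aggregate`, `ensemble` and `featurize` subcommands.

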