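# glut4queue

Stochastic models of cell biology can only be taken seriously once they are
quantitatively compared with data — and the data from experiments such as
GLUT4 translocation assays are sparse (a handful of replicates), destructive
(no paired trajectories), and spread across several protocols that must
constrain one common parameter set. `glut4queue` is a toolkit for exactly
that situation. It provides:

* a discrete-event simulator of **GLUT4 vesicle recycling** as a closed
  queuing network — `N` vesicles cycling endosome → microtubules (M FIFO
  queues of capacity L, with entry blocking) → insulin-gated fusion sites →
  plasma membrane → endosome, with exponential service rates
  (μ_S, μ_M, μ_F, μ_P) and per-site activation probabilities (p_B, p_I);
* the three in-silico experiments used to probe it (insulin **transition**,
  **basal uptake**, **insulin uptake**), with the standard measurement times
  and steady-state normalisation;
* a **hierarchical distance** between model outputs and data, built on
  empirical CDFs: per-time-point two-sample distances (Kolmogorov–Smirnov,
  Kuiper, Cramér–von Mises, Anderson–Darling; Wasserstein-1, signed and
  squared area), aggregated across each time course
  (`D̄_i = (1/τ_i) Σ_j w_ij d(t_ij)`, or L2/max/min), and combined across
  experiments as `Δ = (Σ_i W_i D_i²)^{1/2}`;
* **synthetic-data** generation (7 replicates per time point, with optional
  Gaussian/uniform relative noise and non-negativity re-sampling) and
  **distance-landscape** sweeps over parameter grids, for assessing which
  distances can drive parameter inference.

The headline empirical finding this toolkit reproduces: integrated point
metrics (Wasserstein-1) give a smooth descent to a minimum at the true
parameters and are robust to re-sampling and noise, whereas discrete metrics
(Kolmogorov–Smirnov) plateau away from the truth and vary strongly under
re-sampling — so W1/mean/L2 is the default configuration.

Intended users: modellers fitting stochastic mechanistic models to sparse
multi-protocol time-series data, and anyone needing exact two-sample ECDF
distances on tie-heavy count data.

## Worked example

```python
from glut4queue import (DEFAULT_PARAMS, generate_synthetic_data,
                        hierarchical_distance, normalize_suite,
                        run_protocol_suite)

# 7-replicate synthetic "data" at the reference parameters
data = generate_synthetic_data(DEFAULT_PARAMS, n_reps=7, seed=1)

# 100-replicate model table at the same parameters
model = normalize_suite(run_protocol_suite(DEFAULT_PARAMS, n_runs=100, seed=2))

hd = hierarchical_distance(data.table, model)   # W1 point metric, mean, L2
for e, D in hd.experiment_distances.items():
    print(f"D_{e} = {D:.4f}")
print(f"Delta = {hd.combined:.4f}")

# halving the fusion rate roughly doubles the combined distance
wrong = DEFAULT_PARAMS.replace(rate_fusion=0.025)
model_wrong = normalize_suite(run_protocol_suite(wrong, n_runs=100, seed=2))
print(f"Delta (rate_fusion halved) = {hierarchical_distance(data.table, model_wrong).combined:.4f}")
```

Output:

```
D_basal_uptake = 0.0351
D_insulin_uptake = 0.0398
D_transition = 0.0890
Delta = 0.1037
Delta (rate_fusion halved) = 0.1794
```

`Δ = 0.1037` at the true parameters is the sampling floor — with seven data
replicates the distance is never zero even for the exactly right model —
while the mis-specified fusion rate nearly doubles it; landscape sweeps
(`glut4queue.evaluate_landscape`) map this contrast over whole grids.

The same pipeline is available from the shell:

```bash
glut4queue synth --reps 7 --seed 1 --out data.csv
glut4queue simulate --runs 100 --seed 2 --out model.csv
glut4queue distance --data data.csv --model model.csv --out report.json
glut4queue landscape --axis rate_fusion:0.025:0.075:5 \
                     --axis rate_membrane:0.025:0.075:5 --seed 3 --out landscape.csv
glut4queue noise-study --levels 0,10,20 --resamples 200 --seed 4 --out study.csv
```

Every output carries a sidecar `.meta.json` (seed, parameters, divisors)
sufficient to regenerate it bit-for-bit.

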