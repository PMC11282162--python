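# Methods

## The model

`glut4queue` simulates GLUT4 vesicle recycling in adipocytes as a closed
queuing network with a fixed population of `N` vesicles cycling through four
stations:

1. **Endosome store** — an infinite-server queue; each vesicle independently
   draws an Exp(μ_S) service time representing exit from the endosomal
   compartment and travel to a microtubule.
2. **Microtubules** — `M` parallel FIFO queues of capacity `L` (vesicles
   attach only at the ends and cannot overtake). A vesicle completing
   endosome service picks a microtubule uniformly at random; if that queue is
   full it is *blocked* and re-enters endosome service with a freshly drawn
   Exp(μ_S) time. An unimpeded traversal takes Exp(μ_M).
3. **Fusion sites** — one single-server, zero-buffer queue per microtubule
   with service rate μ_F (SNARE-mediated fusion). Each site is *active* or
   *inactive* for the whole model instance, drawn once per site: one
   persistent uniform `u_m` is drawn, and site `m` is active in the basal
   state iff `u_m < p_B` and in the insulin state iff `u_m < p_I`. Because
   `p_B ≤ p_I`, applying insulin can only activate sites — the model's
   hypothesis for insulin action. Inactive sites accept nothing and block
   their microtubule.
4. **Plasma membrane** — an infinite-server queue with rate μ_P covering
   vesicle reformation and return transport; completion returns the vesicle
   to the endosome.

The surface GLUT4 level is the plasma-membrane queue length in vesicle
units; cumulative uptake is the number of distinct vesicles that have
visited the membrane since an experiment's onset.

### Microtubule departure rule

The model prescribes three behaviours — Exp(μ_M) transit "if unimpeded",
FIFO no-overtaking, and an Exp(L·μ_M) "increment time" for each one-place
advancement behind a departing predecessor — without a single formal rule.
We adopt the recursion

    ready(v) = max(transit_end(v), depart(pred(v)) + increment),

where `increment ~ Exp(L·μ_M)` is drawn at the advancement event that makes
`v` the head, and `v` departs at `max(ready(v), fusion_free)` provided the
site is active. Only the head's increment gates anything, so one increment
is drawn per head-advancement; drawing one per trailing vesicle would
consume more random numbers without changing the law of any departure time.
A vesicle's transit clock keeps running while the queue ahead of it is
blocked (the alternative — pausing it — is an equally admissible reading; we
chose the memoryless-friendlier one and note it here).

### Event handling

A binary-heap event queue processes endosome completions, head-ready events,
fusion completions and membrane completions. Simultaneous events are ordered
by (time, station priority membrane > fusion > microtubule > endosome,
insertion order); with exponential clocks ties have measure zero, so this
choice only pins down bit-level determinism. One master seed yields
per-(run, study-index) `numpy` `SeedSequence` sub-streams, so identical
seeds give bit-identical event sequences and adding runs never perturbs
earlier ones. Exponential and uniform variates are drawn in blocks of 4096
per run purely for speed; the stream remains a pure function of the seed.

## Experimental protocols

Each simulation run executes the three experiments in sequence: 500 time
units of basal warm-up from an all-at-endosome start; **basal uptake**
(visited flags seeded with the current membrane occupants, cumulative unique
visitors sampled at t = 0, 2, 5, 10, 20, 30, 60, 90, 120, 180, 240, 300);
the **transition** (activity switched to the insulin state at t = 0,
membrane level sampled at t = 0, 0.5, 1, 2, 5, 10, 15, 20, 25, 30, 45, 60,
the t = 0 sample taken at the instant of the switch); 500 units to the
insulin steady state; then **insulin uptake** sampled like basal uptake.
Times are dimensionless simulation units. Uptake values are normalised by
the pooled mean of the insulin-uptake samples at t = 300; transition values
by the pooled mean of its own t = 60 samples. Pooling across replicates
(rather than per-run divisors) matches normalising a dataset to "the average
value of the samples" at its final time; data and model tables are
normalised independently, each to its own divisor.

## Distances

Point distances compare the empirical CDFs (Eq. `P(x) = (1/N)·#{x_n ≤ x}`)
of data and model values at one measurement time. Discrete-class metrics —
Kolmogorov–Smirnov `sup|F−G|`, Kuiper `sup(F−G) + sup(G−F)`, two-sample
Cramér–von Mises `(nm/(n+m)²)·Σ_pool (F−G)²` (Anderson's form) and
two-sample Anderson–Darling `(nm/N)·Σ (F−G)²/(H(1−H))` over the pooled
order statistics (Pettitt's form) — are evaluated exactly over the distinct
values of the combined sample, which is sufficient because ECDFs change only
there. Integrated-class metrics — Wasserstein-1 `∫|F−G| dx`, signed area
`∫(F−G) dx` and squared area `∫(F−G)² dx` — are accumulated exactly,
piecewise between consecutive distinct combined values; no binning or
quadrature tolerance is involved. Ties contribute via jump multiplicities;
unequal sample sizes are allowed. Note that under ties the ECDF-sum forms of
CvM/AD differ from midrank-based implementations (e.g. scipy's); count data
make ties routine here, so the ECDF-sum definition is used throughout.

Experiment distances fold the per-time vector with uniform weights `w_j = 1`
by default: mean, L2 norm, maximum or minimum. The combined distance is
`Δ = (Σ_i W_i D_i²)^{1/2}` with unit experiment weights. The default
configuration is W1 point metric, mean aggregation, L2 combination — the
combination with a smooth descent toward the truth and the lowest
re-sampling variance. The same metric/aggregation is applied to every
experiment in a combination, and data/model tables must share measurement
times exactly (mismatches are errors, never interpolated).

## Synthetic data and noise

Synthetic datasets are seven independent protocol-suite runs at known
("true") parameters, normalised as above. Measurement error is emulated as
relative noise, `noisy = v·(1 + ε)`, applied to the normalised values, with
`ε ~ N(0, level²)` or `ε ~ Uniform(−level, +level)`; a draw making the value
negative is rejected and re-drawn (capped at 10⁶ rounds, reachable only at
absurd levels). The uniform support `±level` is our parameterisation — the
"level" of a uniform distribution is not otherwise pinned down — and is
recorded in output metadata so a matched-standard-deviation variant can be
swapped in. The re-sampling study draws fresh 7-replicate datasets and adds
every noise level to the *same* base dataset, separating sampling
variability from noise effects; all levels of one re-sample share one noise
stream, and level 0 reproduces the base exactly.

## Reference parameter set

The package's default truth is

| parameter | value | meaning |
|---|---|---|
| N | 60 | vesicles |
| M | 20 | microtubules / fusion sites |
| L | 3 | microtubule capacity |
| μ_S | 0.2 | endosome exit rate |
| μ_M | 0.5 | microtubule transit rate |
| μ_F | 0.05 | fusion rate |
| μ_P | 0.05 | membrane recycling rate |
| p_B | 0.25 | basal site-activation probability |
| p_I | 0.85 | insulin site-activation probability |

These were chosen by inspecting simulated curves for qualitative
correspondence with the immunofluorescence data: a basal surface level a
modest fraction (~0.25) of the insulin level, a transition essentially
equilibrated within its 60-unit window, sigmoidal uptake saturating within
300 units, and a basal uptake plateau well below the insulin plateau (the
non-recycling-pool signature). Slow fusion and membrane services
(1/μ_F = 1/μ_P = 20 units) make the *shapes* of the normalised curves
sensitive to μ_F and μ_P; because every curve is normalised to a
steady-state mean, purely multiplicative level effects cancel, and a
parameter regime where those rates are not binding yields a flat,
uninformative landscape.

## Problem sizes and numerical choices

Study computations use 7 data replicates and 100 model replicates per table
(model sample sizes beyond 100 change the distances by less than one grid
step, which the test suite verifies directly). Landscape sweeps at desk
scale use 5-point axes spanning [0.5, 1.5]× the true value of each varied
rate (the grid machinery defaults to 21 points per axis for larger
surveys); re-sampling studies use 200 re-samples at 0/10/20% noise where
the full catalogue (0–20% in 12 steps, 1000 re-samples) is not needed.
Parameter recovery is assessed on a 5×5 (μ_F, μ_P) grid: the Δ-argmin is
expected at or grid-adjacent to the truth, the adjacency allowance covering
the non-zero sampling floor of 7-replicate data.

Degenerate inputs are errors, not warnings: empty samples have no ECDF,
non-positive normalisers abort a run, grids containing invalid parameter
points (e.g. `p_B > p_I`) are rejected at construction with the offending
point named, and landscape rows for points whose simulation fails record
the error rather than aborting the sweep. Minima are reported with ties
intact.

## What the synthetic data does and does not emulate

The generator reproduces the sparse sampling (7 replicates, 12 times per
experiment), the destructive/unpaired character of the measurements (each
replicate is an independent run), the normalisation convention, and
homoscedastic relative measurement error. It does not emulate cell-to-cell
averaging of bulk assays (each run is one network instance, so replicate
variance includes the binomial variance of site-activity draws that bulk
averaging would largely remove), labelling chemistry, time-correlated or
heteroscedastic noise, or model misspecification — passing tests show the
distance machinery behaves as designed when the model family is exactly
right, not that the model fits any particular biological dataset.

## Known limitations

* Service distributions are exponential only; no spatial geometry or insulin
  dose–response (two activity phases only).
* The microtubule departure recursion is one admissible formalisation of the
  stated blocking/increment behaviour (see above).
* No parameter-inference engine is included; the landscape tools are the
  intended substrate for one.
* KS-based distances are reported but, at 7-replicate sample sizes, their
  re-sampling variance makes them unsuitable for optimisation — the package
  defaults to W1 accordingly.
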