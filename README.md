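# rddmsim

Stochastic simulation of CHH methylation maintenance by RNA-directed
DNA methylation (RdDM).

In plant euchromatin, asymmetric CHH methylation is halved by every DNA
replication and restored by a self-reinforcing loop: methylated loci
produce 24-nt siRNAs, siRNAs load onto Argonaute (AGO), and AGO:siRNA
complexes search nuclear RNA or DNA for their target locus, where their
cumulative bound time ("dwell") directs new methylation. `rddmsim`
models this loop explicitly — 1000 unique loci, per-locus siRNA
production under linear/saturated/Hill/sigmoid rules, a slightly
limiting AGO pool (0.8 AGO : 1 siRNA), facilitated-diffusion target
search with an occupancy cap of 10 complexes per locus, dwell-driven
reinforcement calibrated in a burn-in generation, and replication
halving — and scores *stability*: whether, after 10 cell cycles, the
methylation distribution across loci is statistically indistinguishable
(two-sample Kolmogorov–Smirnov, p > 0.01) from the first generation's.
It is aimed at quantitative epigenetics researchers who want to map
which production levels, saturation points, reinforcement schedules
(bursty vs steady) and target chemistries (RNA vs DNA) maintain a
low-methylation state (median 8%) across cell divisions.

The core calibration, set during the first ("burn-in") generation,
assumes realised dwell is exactly sufficient for maintenance: with a
median locus at 8% before replication, the dwell it collects must
rebuild the 4 percentage points that replication removes, giving the
exchange rate

    dwell_per_percent = Σᵢ dwellᵢ / (100 · Σᵢ min(mᵢ, s))

over loci i at post-replication methylation mᵢ (s the production
saturation point). See `docs/methods.md` for the full model.

## Worked example

Create a small configuration and run two replicates:

```bash
rddmsim make-fixture calibration --out demo.yaml
rddmsim run --config demo.yaml --replicates 2 --out demo_out
```

```
[10:57:47] running 2 replicate(s), seeds [1, 2]
[10:57:47] replicate 1/2 seed=1 KS p=0.9596 stable=True
[10:57:48] replicate 2/2 seed=2 KS p=0.9596 stable=True
[10:57:48] wrote demo_out/run_trajectory.csv and demo_out/run_summary.json
```

`run_summary.json` records, per replicate, the resolved configuration,
the burn-in calibration, per-generation statistics and the stability
verdict. For replicate 1 of this run:

```
calibration: {'dwell_per_percent': 244.25, 'reference_dwell': 968.63, 'target_gain_pp': 3.97}
stability:   {'ks_statistic': 0.05, 'p_value': 0.9596, 'stable': True}
gen 1  pool 1758  median methylation 0.0766
gen 2  pool 1770  median methylation 0.0764
```

Reading this: the burn-in measured that 244 s of matched AGO:siRNA
dwell raise CHH methylation by one percentage point, so the reference
(median-locus) dwell of 969 s delivers the ~4-point gain that offsets
replication; across two generations the complex pool (~1760 complexes
for 200 loci at production level 300) and the 7.6% median methylation
hold steady, and the final distribution is indistinguishable from the
first generation's (KS D = 0.05, p = 0.96).

Parameter sweeps produce the stability grid (stable replicates out of
seven per condition):

```bash
rddmsim make-fixture sweep_mini --out sweep.yaml
rddmsim sweep --config sweep.yaml --out sweep_out
rddmsim report --from sweep_out
```

The same machinery is available as a library:

```python
from rddmsim import SimulationConfig, ProductionSpec, run_simulation, assess_stability

cfg = SimulationConfig(
    production=ProductionSpec(
        relationship="saturated_linear", production_level=500, saturation_point=0.15
    )
)
res = run_simulation(cfg, seed=1)
report = assess_stability(res.first_generation_methylation, res.final_methylation)
print(report.ks_statistic, report.p_value, report.stable)
```

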