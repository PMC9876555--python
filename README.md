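# cellscaling

Cell lines from the same tumour type can settle at very different
characteristic sizes, and the composition of their proteomes shifts
with that size: some proteins keep a constant mass fraction as cells
get larger, others dilute ("subscale") or concentrate ("superscale").
`cellscaling` is a Python package for studying both sides of this
phenomenon on cell-line panels:

* a **stochastic size-control model** — cells gain area at a constant
  rate β (μm²/min) and divide symmetrically with a propensity
  proportional to their area, R = α·A — with an agent-based population
  simulator, an FFT-convolution distribution propagator, analytic
  cycle-time/added-size laws, and parameter recovery by
  Kullback–Leibler divergence minimization;
* an **omics size-scaling analysis** — mass-fraction normalization,
  per-feature size correlation R and large/small fold change Fc with a
  power-analysis threshold, sub/super-scaling hit calling, relative
  phosphopeptide abundance, mRNA–protein coupling statistics,
  common-language effect sizes, and PLS regression with signed VIP
  feature importances;
* a **synthetic-data generator** that emulates an 11-line melanoma-like
  panel (single-cell areas, peptide/phospho/transcript matrices with
  planted ground truth, growth curves), so the whole pipeline is
  testable without any external data.

## The model in brief

With per-step division probability `P = α·A` and growth `β` per minute,
the cycle time and added area are approximately exponential with rates

```
λ  = −ln(1 − α·A_div) / ln 2        (per min)
λ₂ = λ / β                          (per μm²)
```

The division size then follows the one-generation map
`A_div(n+1) = A_div(n)/2 + β·t_m(n)` with `t_m = 1/λ`, whose fixed
point A\* is stable under size perturbations but shifts when α or the
growth rate changes — cell size is self-correcting, while its set
point is tuned by division signalling.  An `x`-stage cycle yields a
hypoexponential size distribution with mean `2x/λ₂`, variance
`4x/(3λ₂²)`, and CV `1/√(3x)`.

Scaling hits are features with fold change `Fc > 1.5` or `< 0.66`
between lines above/below the panel mean area and `|R| > 0.55`; the
1.5 threshold is the minimal detectable difference of a two-sample
power analysis (n = 5 vs 6 lines, SD 20 scaled units, power 0.95,
features centred at 100).

## Worked example

```python
import cellscaling as cs

params = cs.GrowthDivisionParams(alpha=3.49e-6, beta=0.16)

a_star = cs.find_fixed_point(params)          # 252.0 um^2
lam = cs.cycle_time_rate(params, a_star)      # 1.270e-03 /min

div = cs.propagate_distribution(params)
div.mean(), div.cv()                          # 250.1 um^2, 0.568 (~1/sqrt(3))

sim = cs.run_agent_simulation(params, cs.SimConfig(rng_seed=1))
sim.division_sizes.mean()                     # 253.8 um^2

fit = cs.fit_alpha(sim.division_sizes, beta=0.16)
fit.alpha_hat                                 # 2.96e-06 P/um^2

cs.stages_from_cv(0.25)                       # 5.33 -> ~5-stage cycle
cs.min_detectable_fc()                        # 1.498 -> Fc threshold 1.5
```

The fixed point (252 μm²) is where a line with these parameters
stabilizes its division size; the propagator's stationary distribution
and the 20,000-cell agent simulation agree on that mean to ~2%.
Re-fitting α from the simulated sample by KL minimization recovers it
to within ~15% — the analytic model family is slightly wider than the
agent process, which biases the fitted propensity low by a stable
amount (see `docs/methods.md`).

A command-line entry point chains the stages on synthetic data:

```bash
cellscaling all --seed 11 --outdir out/
# -> panel.csv, peptides.tsv, hits.tsv, vip_ranked.tsv, growth_*.tsv ...
```

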