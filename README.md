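# vmibench

Can correlations between abundance time series recover which virus infects
which microbe?  `vmibench` answers this *in silico*: it simulates virus–
microbe community dynamics with a known bipartite infection network, infers
networks from the sampled series with widely used correlation-based methods,
and scores the inferred networks against the ground truth.  The benchmark's
headline result is negative — every correlation-based method scores an
ROC area (AUC) of about 1/2, i.e. no better than guessing — which matters
to anyone tempted to read co-occurrence or time-lagged correlation networks
from metagenomic time series as infection networks.

## The model

A community of N microbial host populations H_i and N virus populations V_j
interacts through a boolean network M (M_ij = 1 when virus j infects and
lyses host i):

    dH_i/dt = r_i H_i (1 − Σ_i′ a_ii′ H_i′ / K) − H_i Σ_j M_ij φ_ij V_j
    dV_j/dt = V_j Σ_i M_ij φ_ij β_ij H_i − m_j V_j

Hosts grow logistically against a community-wide carrying capacity K with
pairwise competition a; viruses grow by lysing their hosts (adsorption rate
φ_ij, burst size β_ij) and decay at rate m_j.  Life-history traits are
sampled from biologically feasible ranges and then completed so that a
prescribed coexistence state (H\*, V\*) is an exact equilibrium:
the competition matrix pins the virus-free community at carrying capacity,
m_j = Σ_i M_ij φ_ij β_ij H\*_i, and
r_i = (Σ_j M_ij φ_ij V\*_j) / (1 − Σ_i′ a_ii′ H\*_i′ / K).

Time series start from the equilibrium perturbed by ±δ per population,
are sampled every 2 h for 200 h, and log₁₀-transformed.  Inference methods:

* standard Pearson / Spearman / Kendall correlation per host–virus pair;
* time-delayed variants that maximize |r| over virus delays up to 100 h;
* local similarity (LS) scores: maximal sub-interval association of
  normal-score-transformed series with offsets up to 3 samples;
* compositional (log-ratio variance) correlations estimated from
  separately normalized host and virus relative abundances.

Each predicted matrix R is swept over thresholds c (entries ≥ c predict
interaction), giving an ROC against the true network; AUC = 1 is perfect,
AUC = 1/2 is uninformative.

## Worked example

```python
from vmibench.pipeline import ExperimentConfig, run_ensemble, summarize_cvs

cfg = ExperimentConfig.main_text(sizes=(10,), networks_per_structure=3,
                                 master_seed=7)
res = run_ensemble(cfg)
print(res.results.groupby("method")["AUC"].mean().round(3).to_string())
print(summarize_cvs(res).round(3).to_string(index=False))
```

prints

    method
    delayed_pearson    0.579
    elsa               0.472
    pearson            0.468
    sparcc             0.461
    spearman           0.476
     delta  mean_host_cv  mean_virus_cv
       0.3         0.989           0.24

Six N=10 communities (three along a nestedness gradient, three along a
modularity gradient) were simulated at δ = 0.3 and scored with five methods.
Every mean AUC sits near 1/2: knowing that a host and a virus trend
together — even allowing delays, local intervals, or compositional
corrections — tells you almost nothing about whether they interact.  The CV
rows report the variability of the raw trajectories over the sampling
window (hosts fluctuate more than viruses; see `docs/methods.md` for why
these transients amplify).

The full study configuration is `ExperimentConfig()` — sizes 10/25/50,
ten networks per structural gradient, δ ∈ {0.1, 0.3, 0.5} and sampling
every 0.5/2/4 h — and runs in minutes on one CPU.  A command-line interface
mirrors the stages:

    vmibench run-all --sizes 10 25 50 --deltas 0.3 --frequencies 2 \
        --seed 0 --outdir runs/main
    vmibench summarize runs/main/results.csv

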