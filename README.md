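# parbcage

Analysis of bacterial partition-complex assembly from ChIP-seq binding
profiles, built around the *nucleation-and-caging* picture of ParB
spreading.

## The problem

ParB proteins bind the centromere-like *parS* sites of plasmids and
chromosomes and accumulate over >10 kb of flanking DNA — far more than
direct footprints can explain. High-resolution ChIP-seq shows that this
enrichment decays with genomic distance *s* as a power law, which rules out
1-D filament growth and strong-coupling spreading-and-bridging pictures.
Instead, ParB nucleated at *parS* forms a spatially confined cluster, and
flanking DNA is bound stochastically whenever polymer fluctuations loop it
back inside the cluster.

Modeling the DNA as a freely jointed chain of Kuhn length *a* and the
cluster as a Gaussian concentration profile C(r) = κ·exp(−r²/2σ²) of
radius σ, the occupancy at *s* monomers from *parS* is

    P_NC(s) = κ · (1 + a²s / 3σ²)^(−3/2)

so the decay is a pure s^(−3/2) power law at large distance, its shape is
set only by the cluster geometry (σ) and DNA flexibility (*a*), and its
amplitude κ = P_NC(0) is tied to the total number N_t of cluster-bound
ParB through the one-sided integral over the enriched length L:

    N_t = κ · (2/β) · [1 − (1 + βN)^(−1/2)],   β = a²/3σ²,  N = L/a.

Fitting the trial function A0·(1 + A1·ℓ(s))^(−3/2) to an anchored profile
(ℓ the contour length in nm) gives κ = A0 and a = 3σ²·A1.

The package is aimed at people analysing ParB/parS-type ChIP-seq data or
studying polymer models of protein clusters on DNA. It provides:

* `parbcage.polymer_model` — the closed-form occupancy law, the κ ↔ N_t
  normalization, multi-site (union-rule) profiles, cluster-size scenario
  families and the competing 1-D-filament / spreading-and-bridging
  baselines;
* `parbcage.fjc` — a freely-jointed-chain Monte-Carlo benchmark with
  triangular fragment-size smoothing;
* `parbcage.profile_io` — bedGraph/BED I/O, input normalization,
  background estimation, decay-profile anchoring, profile rescaling,
  correlation and roadblock-dip detection;
* `parbcage.fitting` — the nonlinear trial-function fit and parameter
  derivation (κ, *a*, N_t), plus the power-law-exponent diagnostic;
* `parbcage.synthetic` — a ChIP-seq-like data generator with known ground
  truth (Poisson counts, fragment smoothing, roadblocks, barriers);
* a `parbcage` command-line pipeline (`synth`, `simulate`, `profile`,
  `fit`, `compare`) and numbered drivers under `analysis/`.

## Worked example

```python
import numpy as np
from parbcage import (F_PLASMID, ParSSite, SimulationConfig,
                      simulate_profile, fit_nc, total_from_kappa)

p = F_PLASMID                      # sigma=75 nm, a=10 bp, kappa=0.41, L=15 kb
print(total_from_kappa(0.41, p))   # 356.37  -> ~360 ParB on the plasmid

cfg = SimulationConfig(n_monomers=1500, n_conformations=20_000, seed=1)
prof = simulate_profile([ParSSite(0, 10, 0, 1.0)], p, cfg)
fit = fit_nc(prof, p.sigma_nm, window_bp=(1.0, 10_000.0))
print(fit.a0, fit.kuhn_bp)         # 0.4109  10.11
```

The first number is the total cluster-bound ParB implied by the measured
amplitude κ = 0.41 over the 15-kb enriched length. The Monte-Carlo profile
then plays the role of a ChIP-seq measurement: fitting it over the 10-kb
window returns the generating amplitude (0.411 ≈ κ) and Kuhn length
(10.1 bp ≈ 10 bp), confirming that the fit recovers the physics it was
derived from.

The numbered scripts reproduce the full analysis narrative:

```bash
python analysis/01_closed_form_model.py    # N_t = 356.4 (~360); a = 9.7 / 21.5 bp from A1
python analysis/02_fjc_benchmark.py        # 99.9% of offsets within 3 MC standard errors
python analysis/03_fit_parameters.py       # A0 = 0.411, a = 10.1 bp, exponent -1.52
python analysis/04_model_discrimination.py # only fixed-size caging profiles collapse
python analysis/05_synthetic_roundtrip.py  # kappa 4.7%, a 1.4% median recovery error
```

Each writes its tables to `results/`.

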