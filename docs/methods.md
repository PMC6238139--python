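# Methods

## Model

The partition complex is pictured as a spherical ParB cluster nucleated at
*parS*. Two probabilities are multiplied and integrated over space to get
the occupancy of a locus at genomic separation *s* (in Kuhn monomers) from
the nucleation point:

* the looping probability of a Gaussian polymer,
  P(r, s) = (3/2πR²)^{3/2}·exp(−3r²/2R²) with R²(s) = a²s, where *a* is
  the Kuhn length (about twice the DNA persistence length);
* the cluster concentration profile, C(r) = κ·exp(−r²/2σ²), a Gaussian of
  width σ (the cluster radius seen by superresolution microscopy) and
  amplitude κ ∈ [0, 1] (the binding probability at the cluster centre).

The volume integral ∫4πr²·P·C dr evaluates in closed form to

    P_NC(s) = κ·(1 + βs)^{−3/2},    β = a²/3σ²,

so P_NC(0) = κ and P_NC ~ s^{−3/2} once a²s ≫ 3σ². Integrating P_NC over
the one-sided enriched length L (N = L/a monomers) ties the amplitude to
the total cluster-bound ParB count:

    N_t = κ·(2/β)·[1 − (1 + βN)^{−1/2}],

an exact inverse pair with κ(N_t); κ > 1 marks a geometry that cannot hold
the requested number of proteins. We integrate one-sidedly over L because
that convention reproduces the benchmark count N_t ≈ 360 at κ = 0.41 for
the F-plasmid geometry; with N → ∞ the relation degenerates to
κ = (a/σ)²·N_t/6.

Assumptions worth keeping in mind: ideal-chain statistics (no excluded
volume, supercoiling or confinement), a static Gaussian cluster,
independent binding of each monomer, and always-occupied specific sites.
The fitted Kuhn lengths are known to come out low for real bacterial DNA,
plausibly because supercoiling and confinement raise looping probabilities
beyond the ideal-chain value.

## Parameters

| symbol | meaning | unit | default | origin |
|---|---|---|---|---|
| σ (`sigma_nm`) | cluster radius | nm | 75 (F plasmid), 25 (three-site preset) | microscopy |
| a (`kuhn_bp`) | Kuhn length | bp | 10 (F plasmid), 16/22 (chromosomal presets) | fitted |
| κ (`kappa`) | centre binding probability | — | 0.41 (F plasmid), 0.15 (three-site) | fitted |
| L (`enriched_length_bp`) | one-sided enriched length | bp | 15,000 | extent of observed enrichment |
| `nm_per_bp` | contour conversion | nm/bp | 0.34 | B-DNA rise |
| fragment size | ChIP library fragment | bp | 280 (single-site), 304 (three-site) | library statistics |
| ParB footprint | one binding motif | bp | 16 | motif length |

## Monte-Carlo benchmark

Chains are sampled as freely jointed chains: independent uniform bond
directions (normalized Gaussian triples) of fixed length *a*. For each
conformation, every monomer binds with probability
1 − Π_k(1 − w_k·C(r_k)) over nucleation sites k, with r_k the spatial
distance to site k's monomer *in that same conformation*; site monomers
are pinned at their plateau weight w_k. By default the exact Bernoulli
probability is averaged per conformation rather than flipping one coin per
monomer — same expectation, much lower variance; the literal coin-flip
scheme is available (`exact_probability=False`) and agrees within its own
Monte-Carlo error. The default 20,000 conformations give a relative
standard error below 1% near the nucleation site at κ ≈ 0.4; the test
suite uses 2,000–6,000 conformations, which keeps the whole suite in
seconds while leaving the 3-standard-error agreement band intact.
Randomness comes from a single seeded `numpy` PCG64 generator; the seed is
recorded in output metadata, and fixed seeds give bit-identical profiles.

Fragment-size smoothing follows the read-counting convention for sonicated
libraries: each bound ParB contributes a triangle of apex 1 at its position
falling to 0 at ± the mean fragment size. We implement it as convolution
with that kernel, normalized by the local kernel mass so a flat profile is
unchanged (the average over fragment positions), with optional
re-anchoring to 1 at the profile anchor. Whether to renormalize after
smoothing is a convention; we re-anchor normalized profiles so smoothed
and unsmoothed curves remain comparable.

## Coverage processing and anchoring

Input tracks are scaled to the IP total read count. Background is the
median per-bp count outside ±25 kb of the site centre; it is subtracted
with clamping at zero before normalization. Two anchor conventions exist
and differ by one bp — with materially different meanings on clean data:

* **first bp downstream** of the last specific repeat: the reference is
  the *non-specific* signal, so the normalized profile starts at 1 and a
  trial-function fit returns A0 ≈ 1 regardless of κ;
* **last repeat bp**: the reference is the always-occupied specific
  plateau, so the flank is expressed in absolute occupancy units and the
  fitted A0 equals κ.

On real, fragment-smeared coverage the two anchors carry nearly the same
value, which is why the distinction is invisible there. The default is the
downstream convention; κ-recovery analyses use the plateau convention, and
fits on absolute-occupancy profiles start at 1 bp so the specific point
itself is excluded from the non-specific decay.

## Fitting

Bounded nonlinear least squares (`scipy.optimize.curve_fit`, trust-region
reflective) on P(s) = A0·(1 + A1·ℓ(s))^{−3/2}, with ℓ(s) = 0.34·s nm the
contour length, A0 ∈ (0, 1], A1 ∈ (0, 1] nm⁻¹, initialized at the anchor
density and A1 = 2×10⁻⁴ nm⁻¹. The default window is 0–10 kb; the loss is
unweighted squared error on the linear scale, with a log-scale option, and
dip intervals can be masked. A1 only balances dimensionally if *s* enters
as contour length in nm, which the 0.34 nm/bp conversion supplies;
consistency check: A1 = 1.96×10⁻⁴ nm⁻¹ at σ = 75 nm gives
a = 3σ²A1 = 3.31 nm ≈ 9.7 bp, and A1 = 4.33×10⁻⁴ nm⁻¹ gives 7.31 nm
≈ 21.5 bp. Amplitude rescaling of the profile moves only A0, never A1 —
the decay shape is independent of the ParB amount.

The multi-site fit is semi-quantitative by construction: site weights are
read off the observed peak heights (tallest = 1), then (κ, a) are fitted
on the union model; a warning flags sites closer than the fragment width,
where peaks are not independently resolvable.

The exponent diagnostic regresses log density on log(1 + βs) by OLS; the
caging law gives −3/2 exactly, plateau-type baselines give ≈ 0 at large s.

## Synthetic data

The generator emulates the structure of partition-complex ChIP-seq: an IP
track whose expected value is depth × (multi-site occupancy) ×
(multiplicative roadblock suppressions), smoothed by the triangular
fragment kernel, plus a flat background; an input track at the background
mean; per-bp Poisson counts (negative-binomial overdispersion optional).
Default study conditions: the F-plasmid geometry above, one 402-bp repeat
block, depth 500 reads/bp at full occupancy, background 10 reads/bp,
fragment 280 bp; a three-site preset mirrors the chromosome-1 setting
(σ = 25 nm, a = 16 bp, κ = 0.15, weights 1/0.9/0.6, fragment 304 bp).

Two generator design choices matter for interpretation:

* **Finite enrichment extent.** The non-specific signal is truncated at L
  from the nearest site, so distal flanks sit at pure background. The
  s^{−3/2} tail otherwise decays so slowly that, at desk-scale windows, it
  leaks past the background-exclusion zone and corrupts the median-flank
  background estimate (we measured a 5-fold overestimate and a ~65% Kuhn
  bias without truncation). Observed profiles likewise end at basal level
  at ~9–15 kb.
* **Recovery runs use unsmoothed tracks** (fragment 0) and the plateau
  anchor. Fragment smearing mixes the specific plateau into the anchor
  neighbourhood, which biases any anchor-normalized amplitude; with
  smearing on, κ is only semi-quantitative — as is the case for real
  multi-site chromosomal data.

A barrier variant truncates one flank at a coordinate, emulating exclusion
by a large nucleoprotein complex (replication-initiator arrays, rRNA
operons).

What passing synthetic tests do **not** show about real data: mapping and
GC bias, copy-number variation, overdispersion beyond the optional
negative binomial, read-level artefacts, and any deviation of real
chromatin from ideal-chain statistics are all outside the generator.

## Roadblock dips

`detect_dips` smooths the flank-normalized profile with a ~51-bp rolling
mean, divides by the unit-amplitude model decay, and reports maximal
intervals at least 50 bp wide where the ratio falls below 0.5. On
replicate synthetic datasets sharing a roadblock, the detected intervals
coincide (Jaccard > 0.9). The enrichment edge at L also appears as a
"dip" against the untruncated model — a real feature of finite
enrichment, which edge-window analyses should exclude.

## Numerical choices and degenerate inputs

Genomic intervals are 0-based half-open; densities are evaluated at
integer bp offsets; bedGraph conventions are preserved on I/O, with
overlap and malformed-record detection by line number. κ outside [0, 1],
non-positive separations in the looping density, empty site lists,
zero-variance correlation inputs, anchors at or below background, and
identically-zero rescaling targets all raise explicit errors. The
κ ↔ N_t pair is closed-form, hence inverse to ~1e−15; the occupancy law
matches direct quadrature of the volume integral to better than 1e−8.
Least-squares rescaling between profiles uses the closed form Σtr/Σt²,
which reduces to the eyeballed factors on noiseless data and is
reproducible on noisy data.

## Problem sizes

Analyses and the acceptance computation use 1,500-monomer chains (15 kb at
a = 10 bp) with 20,000 conformations (~10 s on one core); the test suite
scales chains and replicate counts down (300–1,500 monomers, 2,000–6,000
conformations, 20-seed recovery ensembles) so the full suite runs in
seconds. Recovery criteria are medians over 20 seeds at the default study
conditions.

## Known limitations

* No supercoiling, confinement or excluded-volume corrections; fitted
  Kuhn lengths are effective, not literal, polymer constants.
* The union rule for overlapping clusters (1 − Π(1 − p_k)) is a modeling
  choice that keeps densities probabilities; the behaviour of genuinely
  interacting clusters is not derived.
* The competing-model baselines are schematic (triangle with 1/m slope;
  sharp drop to an m-proportional plateau), intended for shape
  discrimination only.
* No uncertainty quantification beyond seed-replicate spread.
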