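"""Closed-form nucleation-and-caging occupancy model and competing baselines.

The model: ParB nucleates at *parS* and forms a spatially confined cluster
of Gaussian radial concentration C(r) = κ·exp(−r²/2σ²). Flanking DNA,
treated as a Gaussian polymer of Kuhn length a, visits the cluster with the
looping probability P(r, s) and picks up ParB there. Integrating the product
over space gives the occupancy at genomic separation s (in monomers):

    P_NC(s) = κ · (1 + a²s/3σ²)^(-3/2)

which decays asymptotically as s^(-3/2) and has P_NC(0) = κ. Integrating
P_NC over the one-sided enriched length ties κ to the total cluster-bound
ParB count N_t, giving the amplitude a physical normalization.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .types import BindingProfile, ModelParams, ParSSite, ScenarioSpec

__all__ = [
    "loop_contact_probability",
    "cluster_concentration",
    "nc_density",
    "total_from_kappa",
    "kappa_from_total",
    "multi_site_density",
    "spreading_bridging_profile",
    "one_d_spreading_profile",
    "scenario_family",
]

#: default ParB footprint on DNA, bp (one binding motif)
PARB_FOOTPRINT_BP = 16.0


def loop_contact_probability(r, s, a):
    """Probability density (per nm³) that two loci s monomers apart sit at
    spatial distance r, for a Gaussian chain of Kuhn length ``a`` nm.

    The mean-squared separation is R²(s) = a²s; the density is the
    isotropic Gaussian (3/2πR²)^(3/2)·exp(−3r²/2R²), normalized over 3-space.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.asarray(s) <= 0):
        raise ValueError("genomic separation s must be positive (R undefined at s<=0)")
    if a <= 0:
        raise ValueError("Kuhn length a must be positive")
    if np.any(r < 0):
        raise ValueError("radial distance r must be >= 0")
    r2_mean = a * a * np.asarray(s, dtype=float)
    pref = (3.0 / (2.0 * np.pi * r2_mean)) ** 1.5
    out = pref * np.exp(-3.0 * r**2 / (2.0 * r2_mean))
    return out if out.ndim else float(out)


def cluster_concentration(r, kappa: float, sigma_nm: float):
    """Binding probability at radial distance ``r`` nm from the cluster
    centre: κ·exp(−r²/2σ²), the Gaussian reservoir profile of the cluster."""
    if not (0.0 <= kappa <= 1.0):
        raise ValueError(f"kappa is a probability amplitude; must be in [0, 1], got {kappa}")
    if sigma_nm <= 0:
        raise ValueError("sigma_nm must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radial distance r must be >= 0")
    out = kappa * np.exp(-(r**2) / (2.0 * sigma_nm**2))
    return out if out.ndim else float(out)


def nc_density(s_bp, params: ModelParams):
    """Nucleation-and-caging occupancy at genomic distance ``s_bp`` from parS.

    Evaluates κ·(1 + a²s_m/3σ²)^(-3/2) with the separation converted to
    monomers, s_m = s_bp / kuhn_bp. Strictly decreasing in s; equals κ at 0.
    """
    s_bp = np.asarray(s_bp, dtype=float)
    if np.any(s_bp < 0):
        raise ValueError("genomic distance must be >= 0")
    s_m = s_bp / params.kuhn_bp
    out = params.kappa * (1.0 + params.beta * s_m) ** -1.5
    return out if out.ndim else float(out)


def _depletion_factor(params: ModelParams) -> float:
    """(2/β)·[1 − (1+βN)^(-1/2)]: the integral of the unit-amplitude decay
    over the one-sided enriched length, in monomers."""
    n = params.enriched_length_bp / params.kuhn_bp
    b = params.beta
    return (2.0 / b) * (1.0 - (1.0 + b * n) ** -0.5)


def total_from_kappa(kappa: float, params: ModelParams) -> float:
    """Total cluster-bound ParB implied by the amplitude κ.

    One-sided closed-form integral of the occupancy law over the enriched
    length L (N = L/a monomers):

        N_t = ∫₀^N P_NC(s) ds = κ·(2/β)·[1 − (1+βN)^(-1/2)],  β = a²/3σ².
    """
    if not (0.0 <= kappa <= 1.0):
        raise ValueError(f"kappa must be in [0, 1], got {kappa}")
    return kappa * _depletion_factor(params)


def kappa_from_total(n_total: float, params: ModelParams) -> float:
    """Amplitude κ implied by a total ParB count; exact inverse of
    :func:`total_from_kappa`.

    Raises if the geometry cannot accommodate that many proteins (κ > 1):
    at fixed σ, a chain with too long a Kuhn length returns to the cluster
    too rarely to carry the requested N_t.
    """
    if n_total < 0:
        raise ValueError("n_total must be >= 0")
    kappa = n_total / _depletion_factor(params)
    if kappa > 1.0:
        raise ValueError(
            f"n_total={n_total} requires kappa={kappa:.3f} > 1: "
            "infeasible for this cluster geometry"
        )
    return kappa


def multi_site_density(
    positions_bp, sites: Sequence[ParSSite], params: ModelParams
) -> BindingProfile:
    """Occupancy over genomic positions for one or more nucleation sites.

    Each site contributes p_k(x) = weight_k·P_NC(|x − centre_k|) from its own
    (non-interacting) cluster; within a site's specific-repeat interval the
    contribution is the plateau weight_k itself (the specific complex is
    always bound). Contributions combine by the independent-union rule
    1 − Π(1 − p_k), which keeps the density a probability for any geometry.
    """
    if len(sites) == 0:
        raise ValueError("at least one parS site is required")
    x = np.asarray(positions_bp, dtype=float)
    one_minus = np.ones_like(x)
    for site in sites:
        s = np.abs(x - site.center_bp)
        p = site.weight * nc_density(s, params)
        in_repeat = (x >= site.repeat_start_bp) & (x < site.repeat_end_bp)
        p = np.where(in_repeat, site.weight, p)
        one_minus *= 1.0 - p
    density = 1.0 - one_minus
    anchor = max(sites, key=lambda st: st.weight).center_bp
    return BindingProfile(x - anchor, density, anchor_bp=anchor, normalized=False)


def spreading_bridging_profile(
    m: float,
    positions_bp,
    footprint_bp: float = PARB_FOOTPRINT_BP,
    center_bp: float = 0.0,
) -> BindingProfile:
    """Spreading-and-bridging baseline: in the strong-coupling limit all m
    ParB condense against parS, giving a triangular profile whose slope
    scales as 1/m — density 1 at parS falling linearly to 0 once the m
    footprints are exhausted."""
    if m <= 0:
        raise ValueError("m must be positive")
    x = np.asarray(positions_bp, dtype=float)
    s = np.abs(x - center_bp)
    density = np.maximum(0.0, 1.0 - s / (m * footprint_bp))
    return BindingProfile(x - center_bp, density, anchor_bp=int(center_bp))


def one_d_spreading_profile(
    m: float,
    plateau_per_particle: float,
    positions_bp,
    drop_bp: float = PARB_FOOTPRINT_BP,
    center_bp: float = 0.0,
) -> BindingProfile:
    """1-D filament baseline: nearest-neighbour interactions alone cannot
    cluster particles in 1-D, so the density drops off sharply at parS and
    the remaining ParB sit at a uniform level proportional to their number.

    ``plateau_per_particle`` is the far-field density contributed per ParB;
    the plateau min(1, m·plateau_per_particle) is approached within a few
    ``drop_bp`` of the site.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if not (0.0 <= plateau_per_particle <= 1.0):
        raise ValueError("plateau_per_particle must be in [0, 1]")
    x = np.asarray(positions_bp, dtype=float)
    s = np.abs(x - center_bp)
    plateau = min(1.0, m * plateau_per_particle)
    density = plateau + (1.0 - plateau) * np.exp(-s / drop_bp)
    return BindingProfile(x - center_bp, density, anchor_bp=int(center_bp))


def scenario_family(
    spec: ScenarioSpec, params: ModelParams, positions_bp=None
) -> list[BindingProfile]:
    """Occupancy profiles predicted under ParB-amount variation.

    ``constant_size``: σ fixed, amplitude proportional to the ParB ratio —
    after dividing by amplitude all profiles collapse onto one curve.
    ``constant_concentration``: compact clusters of fixed ParB density, so
    σ(m) = σ_ref·(m/m_ref)^(1/3) and the decay shape itself changes.

    Amplitudes are relative to the reference κ and may exceed 1 for large
    ratios; the family is a schematic shape comparison, not a probability.
    """
    if positions_bp is None:
        positions_bp = np.arange(0.0, params.enriched_length_bp + 1.0, 10.0)
    x = np.asarray(positions_bp, dtype=float)
    s_m = np.abs(x) / params.kuhn_bp
    profiles = []
    for ratio in spec.ratios:
        if spec.mode == "constant_size":
            amp = params.kappa * ratio
            beta = params.beta
        else:  # constant_concentration
            amp = params.kappa
            sigma = params.sigma_nm * ratio ** (1.0 / 3.0)
            beta = params.kuhn_nm**2 / (3.0 * sigma**2)
        density = amp * (1.0 + beta * s_m) ** -1.5
        profiles.append(BindingProfile(x, density, anchor_bp=0))
    return profiles
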