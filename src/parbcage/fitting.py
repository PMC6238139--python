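"""Nonlinear fit of the occupancy law to normalized decay profiles.

Trial function (lengths in nm via the contour conversion ℓ(s) = nm_per_bp·s):

    P(s) = A0 · (1 + A1·ℓ(s))^(-3/2)

with A0 = κ (dimensionless) and A1 = a/3σ² (nm⁻¹), so the Kuhn length is
recovered as a = 3σ²·A1 and the total cluster-bound ParB count follows from
κ through the closed-form normalization over the enriched length.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .types import NM_PER_BP, BindingProfile, FitResult, ModelParams, ParSSite
from .polymer_model import kappa_from_total, multi_site_density, total_from_kappa

__all__ = [
    "fit_nc",
    "derive_params",
    "fit_multi_parS",
    "fit_powerlaw_exponent",
    "FitError",
]

DEFAULT_WINDOW_BP = (0.0, 10_000.0)


class FitError(RuntimeError):
    """Fit failed to converge or landed outside the physical domain."""


def _window_data(
    profile: BindingProfile, window_bp, mask_intervals=None
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = window_bp
    sel = (profile.offsets_bp >= lo) & (profile.offsets_bp <= hi)
    if mask_intervals:
        for a, b in mask_intervals:
            sel &= ~((profile.offsets_bp >= a) & (profile.offsets_bp < b))
    s = profile.offsets_bp[sel]
    y = profile.density[sel]
    if s.size < 3:
        raise FitError("fewer than 3 profile points in the fit window")
    return s, y


def fit_nc(
    profile: BindingProfile,
    sigma_nm: float,
    window_bp: tuple[float, float] = DEFAULT_WINDOW_BP,
    nm_per_bp: float = NM_PER_BP,
    enriched_length_bp: float = 15_000.0,
    log_weight: bool = False,
    mask_intervals: Sequence[tuple[float, float]] | None = None,
) -> FitResult:
    """Bounded least-squares fit of A0·(1 + A1·ℓ(s))^(-3/2) to a profile.

    ``sigma_nm`` is held fixed (known from microscopy); A0 and A1 are free.
    ``log_weight`` switches the loss to squared error on log densities
    (useful when the far tail should carry weight); ``mask_intervals``
    excludes offset ranges (e.g. dips flagged by ``detect_dips``).
    Returns a :class:`FitResult` with derived κ, Kuhn length and N_t.
    """
    s, y = _window_data(profile, window_bp, mask_intervals)
    ell = nm_per_bp * s  # contour length in nm

    def model(ell, a0, a1):
        return a0 * (1.0 + a1 * ell) ** -1.5

    p0 = (float(np.clip(y[np.argmin(s)], 1e-3, 1.0)), 2e-4)
    bounds = ([1e-12, 1e-12], [1.0, 1.0])
    try:
        if log_weight:
            pos = y > 0
            if pos.sum() < 3:
                raise FitError("log-weighted fit needs >= 3 positive densities")
            popt, _ = curve_fit(
                lambda e, a0, a1: np.log(model(e, a0, a1)),
                ell[pos], np.log(y[pos]), p0=p0, bounds=bounds, maxfev=10_000,
            )
        else:
            popt, _ = curve_fit(model, ell, y, p0=p0, bounds=bounds, maxfev=10_000)
    except RuntimeError as exc:
        raise FitError(f"nonlinear fit did not converge: {exc}") from None

    a0, a1 = float(popt[0]), float(popt[1])
    if not (0.0 < a0 <= 1.0):
        raise FitError(f"A0={a0} outside (0, 1] at the optimum")
    resid = y - model(ell, a0, a1)
    kuhn_nm = 3.0 * sigma_nm**2 * a1
    kuhn_bp = kuhn_nm / nm_per_bp
    params = ModelParams(
        sigma_nm=sigma_nm,
        kuhn_bp=max(1.0, kuhn_bp),
        kappa=a0,
        n_total=0.0,
        enriched_length_bp=enriched_length_bp,
        nm_per_bp=nm_per_bp,
    )
    n_total = total_from_kappa(a0, params)
    return FitResult(
        a0=a0,
        a1_per_nm=a1,
        kappa=a0,
        kuhn_nm=kuhn_nm,
        kuhn_bp=kuhn_bp,
        n_total=n_total,
        window_bp=(float(window_bp[0]), float(window_bp[1])),
        sse=float(np.dot(resid, resid)),
        sigma_nm=sigma_nm,
        nm_per_bp=nm_per_bp,
    )


def derive_params(
    fit: FitResult, sigma_nm: float, enriched_length_bp: float = 15_000.0
) -> ModelParams:
    """Assemble the physical parameter set implied by a fit.

    κ = A0 and a = 3σ²A1 directly; N_t follows from the closed-form
    normalization over the enriched length. Raises if κ > 1.
    """
    if fit.kappa > 1.0:
        raise ValueError(f"kappa={fit.kappa} > 1: infeasible amplitude")
    params = ModelParams(
        sigma_nm=sigma_nm,
        kuhn_bp=max(1.0, fit.kuhn_bp),
        kappa=fit.kappa,
        n_total=0.0,
        enriched_length_bp=enriched_length_bp,
        nm_per_bp=fit.nm_per_bp,
    )
    return params.replace(n_total=total_from_kappa(fit.kappa, params))


def fit_multi_parS(
    profile: BindingProfile,
    sites: Sequence[ParSSite],
    sigma_nm: float,
    window_bp: tuple[float, float] | None = None,
    nm_per_bp: float = NM_PER_BP,
    enriched_length_bp: float = 15_000.0,
    fragment_bp: float = 0.0,
) -> tuple[ModelParams, list[float]]:
    """Semi-quantitative fit for several nucleation sites.

    Relative site weights are fixed from the observed peak heights at each
    site centre (tallest = 1), as read off the profile; the remaining free
    parameters (κ, a) are then fitted on the union model. Warns if two
    sites are closer than the fragment width (peaks not resolvable).
    """
    if len(sites) < 2:
        raise ValueError("fit_multi_parS needs >= 2 sites; use fit_nc for one")
    centers = np.array([s.center_bp for s in sites], dtype=float)
    if fragment_bp > 0:
        gaps = np.diff(np.sort(centers))
        if np.any(gaps < fragment_bp):
            warnings.warn(
                "inter-site distance below the fragment width; peak heights "
                "(hence weights) are not independently resolvable",
                stacklevel=2,
            )

    peak = np.array([profile.value_at(c - profile.anchor_bp) for c in centers])
    if peak.max() <= 0:
        raise ValueError("no positive peak heights at the site centres")
    weights = (peak / peak.max()).tolist()
    sized = [
        ParSSite(s.repeat_start_bp, s.repeat_end_bp, s.center_bp, max(w, 1e-6))
        for s, w in zip(sites, weights)
    ]

    positions = profile.offsets_bp + profile.anchor_bp
    if window_bp is None:
        sel = np.ones(positions.size, dtype=bool)
    else:
        sel = (profile.offsets_bp >= window_bp[0]) & (profile.offsets_bp <= window_bp[1])
    x = positions[sel]
    y = profile.density[sel]

    def model(x, a0, a1):
        kuhn_bp = max(1.0, 3.0 * sigma_nm**2 * a1 / nm_per_bp)
        p = ModelParams(
            sigma_nm=sigma_nm, kuhn_bp=kuhn_bp, kappa=a0,
            n_total=0.0, enriched_length_bp=enriched_length_bp, nm_per_bp=nm_per_bp,
        )
        dens = multi_site_density(x, sized, p).density
        i0 = int(np.argmin(np.abs(x - profile.anchor_bp)))
        ref = dens[i0]
        return dens / ref if ref > 0 else dens

    try:
        popt, _ = curve_fit(
            model, x, y, p0=(0.3, 2e-4), bounds=([1e-12, 1e-12], [1.0, 1.0]),
            maxfev=10_000,
        )
    except RuntimeError as exc:
        raise FitError(f"multi-site fit did not converge: {exc}") from None
    a0, a1 = float(popt[0]), float(popt[1])
    kuhn_bp = 3.0 * sigma_nm**2 * a1 / nm_per_bp
    params = ModelParams(
        sigma_nm=sigma_nm, kuhn_bp=max(1.0, kuhn_bp), kappa=a0,
        n_total=0.0, enriched_length_bp=enriched_length_bp, nm_per_bp=nm_per_bp,
    )
    params = params.replace(n_total=total_from_kappa(a0, params))
    return params, weights


def fit_powerlaw_exponent(
    profile: BindingProfile,
    params: ModelParams,
    window_bp: tuple[float, float] = DEFAULT_WINDOW_BP,
) -> float:
    """OLS slope of log density against log(1 + a²s_m/3σ²).

    For data generated by the occupancy law this is the power-law exponent
    −3/2; flat (plateau-type) profiles give a slope near 0 at large s.
    """
    s, y = _window_data(profile, window_bp)
    if np.any(y <= 0):
        raise ValueError("power-law diagnostic needs strictly positive densities")
    x = np.log1p(params.beta * np.abs(s) / params.kuhn_bp)
    if np.ptp(x) == 0:
        raise ValueError("degenerate abscissa in the fit window")
    slope, _ = np.polyfit(x, np.log(y), 1)
    return float(slope)
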