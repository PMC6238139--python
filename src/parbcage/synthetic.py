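"""Synthetic ChIP-seq-like coverage with known ground truth.

Emulates the structure of partition-complex ChIP-seq experiments: an input
track at flat background, and an IP track with a plateau over the specific
binding repeats, power-law-decaying flanks from the occupancy law,
multiplicative dips at roadblock loci, triangular fragment smoothing, and
per-bp Poisson counting noise. Every dataset carries the generating truth
so pipeline stages can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import CoverageTrack, ModelParams, ParSSite, F_PLASMID, VIBRIO_CHR1
from .polymer_model import multi_site_density
from .fjc import smooth_with_fragments

__all__ = ["SyntheticTruth", "generate_dataset", "generate_barrier_variant",
           "f_plasmid_truth", "vibrio_truth"]


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters of a synthetic dataset.

    ``depth`` is the expected IP reads/bp for a fully occupied bp (density
    1), ``background`` the flat nonspecific level added to the IP and used
    as the input mean. Roadblocks are (interval, suppression) pairs: the
    occupancy inside the interval is multiplied by the suppression factor
    in [0, 1). ``dispersion`` switches Poisson noise to negative binomial
    with that gamma-mixture shape (None = pure Poisson).
    """

    params: ModelParams = F_PLASMID
    sites: Sequence[ParSSite] = field(
        default_factory=lambda: (ParSSite(49_799, 50_201, 50_000, 1.0),)
    )
    roadblocks: Sequence[tuple[tuple[int, int], float]] = ()
    depth: float = 500.0
    background: float = 10.0
    fragment_bp: float = 280.0
    seed: int = 0
    chrom: str = "synthetic"
    window_start_bp: Optional[int] = None
    window_end_bp: Optional[int] = None
    input_mean: Optional[float] = None
    dispersion: Optional[float] = None

    def __post_init__(self) -> None:
        if self.depth < 0 or self.background < 0:
            raise ValueError("depth and background must be >= 0")
        if self.depth and self.depth <= self.background:
            raise ValueError("depth must exceed background")
        for (lo, hi), f in self.roadblocks:
            if not (0.0 <= f < 1.0):
                raise ValueError("roadblock suppression factors must be in [0, 1)")
            if hi <= lo:
                raise ValueError("roadblock interval must be non-empty")

    def window(self) -> tuple[int, int]:
        pad = int(self.params.enriched_length_bp + 10_000)
        lo = self.window_start_bp
        hi = self.window_end_bp
        if lo is None:
            lo = min(s.repeat_start_bp for s in self.sites) - pad
        if hi is None:
            hi = max(s.repeat_end_bp for s in self.sites) + pad
        return int(lo), int(hi)

    def to_dict(self) -> dict:
        lo, hi = self.window()
        return {
            "params": {
                "sigma_nm": self.params.sigma_nm,
                "kuhn_bp": self.params.kuhn_bp,
                "kappa": self.params.kappa,
                "n_total": self.params.n_total,
                "enriched_length_bp": self.params.enriched_length_bp,
                "nm_per_bp": self.params.nm_per_bp,
            },
            "sites": [
                {
                    "repeat_start_bp": s.repeat_start_bp,
                    "repeat_end_bp": s.repeat_end_bp,
                    "center_bp": s.center_bp,
                    "weight": s.weight,
                }
                for s in self.sites
            ],
            "roadblocks": [
                {"start_bp": lo_, "end_bp": hi_, "suppression": f}
                for (lo_, hi_), f in self.roadblocks
            ],
            "depth": self.depth,
            "background": self.background,
            "fragment_bp": self.fragment_bp,
            "seed": self.seed,
            "chrom": self.chrom,
            "window_bp": [lo, hi],
            "input_mean": self.input_mean,
            "dispersion": self.dispersion,
        }


def f_plasmid_truth(**overrides) -> SyntheticTruth:
    """F-plasmid-like single-site dataset (σ=75 nm, a=10 bp, κ=0.41,
    one-sided enrichment 15 Kbp, fragment 280 bp)."""
    return SyntheticTruth(**overrides)


def vibrio_truth(**overrides) -> SyntheticTruth:
    """Three-site chromosome-1-like dataset (σ=25 nm, a=16 bp, κ=0.15,
    site weights 1/0.9/0.6, fragment 304 bp)."""
    sites = (
        ParSSite(62_422, 62_454, 62_438, 1.0),
        ParSSite(64_422, 64_454, 64_438, 0.9),
        ParSSite(66_422, 66_454, 66_438, 0.6),
    )
    defaults = dict(params=VIBRIO_CHR1, sites=sites, fragment_bp=304.0)
    defaults.update(overrides)
    return SyntheticTruth(**defaults)


def expected_ip_signal(
    truth: SyntheticTruth, barrier: tuple[str, int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(positions, expected per-bp IP reads) before counting noise.

    depth × occupancy × roadblock suppressions, truncated at an optional
    barrier, smoothed by the triangular fragment kernel, plus background.
    """
    lo, hi = truth.window()
    pos = np.arange(lo, hi)
    dens = multi_site_density(pos, list(truth.sites), truth.params).density
    # enrichment has finite extent: the cluster does not reach beyond the
    # enriched length, so distal flanks sit at pure background
    centers = np.array([s.center_bp for s in truth.sites], dtype=float)
    dist = np.min(np.abs(pos[:, None] - centers[None, :]), axis=1)
    dens = np.where(dist > truth.params.enriched_length_bp, 0.0, dens)
    for (rlo, rhi), f in truth.roadblocks:
        dens = np.where((pos >= rlo) & (pos < rhi), dens * f, dens)
    if barrier is not None:
        side, coord = barrier
        if side == "left":
            dens = np.where(pos < coord, 0.0, dens)
        elif side == "right":
            dens = np.where(pos >= coord, 0.0, dens)
        else:
            raise ValueError("barrier side must be 'left' or 'right'")
    if truth.fragment_bp > 0:
        dens = smooth_with_fragments(dens, truth.fragment_bp, 1.0)
    return pos, truth.depth * dens + truth.background


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, dispersion) -> np.ndarray:
    if dispersion is None:
        return rng.poisson(mean).astype(float)
    # gamma-Poisson mixture: variance = mean + mean^2/dispersion
    lam = rng.gamma(shape=dispersion, scale=np.maximum(mean, 1e-12) / dispersion)
    return rng.poisson(lam).astype(float)


def generate_dataset(
    truth: SyntheticTruth, barrier: tuple[str, int] | None = None
) -> tuple[CoverageTrack, CoverageTrack, dict]:
    """Draw an (IP, input) coverage pair plus the truth record.

    Counts are per-bp Poisson (or negative binomial) around the expected
    signal; the input is flat at ``input_mean`` (default: the background).
    Bit-identical across runs for a fixed seed.
    """
    rng = np.random.default_rng(truth.seed)
    pos, mean_ip = expected_ip_signal(truth, barrier)
    lo, hi = int(pos[0]), int(pos[-1]) + 1
    ip_counts = _draw_counts(rng, mean_ip, truth.dispersion)
    input_mean = truth.background if truth.input_mean is None else truth.input_mean
    inp_counts = _draw_counts(rng, np.full(pos.size, float(input_mean)), truth.dispersion)
    ip = CoverageTrack(truth.chrom, lo, hi, ip_counts)
    inp = CoverageTrack(truth.chrom, lo, hi, inp_counts)
    record = truth.to_dict()
    if barrier is not None:
        record["barrier"] = {"side": barrier[0], "coordinate_bp": barrier[1]}
    return ip, inp, record


def generate_barrier_variant(
    truth: SyntheticTruth, side: str, barrier_offset_bp: float | None = None
) -> tuple[CoverageTrack, CoverageTrack, dict]:
    """Dataset with one flank truncated at a barrier.

    Emulates a large nucleoprotein complex (e.g. a replication-initiator
    array or an rRNA operon) that excludes the cluster beyond a coordinate:
    occupancy on the chosen side of ``centre + barrier_offset_bp`` is set
    to background level. ``barrier_offset_bp=None`` reproduces
    :func:`generate_dataset` exactly.
    """
    if barrier_offset_bp is None:
        return generate_dataset(truth)
    anchor = max(truth.sites, key=lambda s: s.weight).center_bp
    return generate_dataset(truth, barrier=(side, int(anchor + barrier_offset_bp)))
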