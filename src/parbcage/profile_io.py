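"""Coverage-track plumbing: bedGraph/BED I/O, normalization, decay profiles.

Turns raw per-bp ChIP-seq coverage (IP + input) into the normalized decay
profile the model is fitted to: total-read normalization of the input,
median-flank background subtraction, and anchoring of the density to 1 at
the first bp downstream of the last specific binding repeat.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .types import BindingProfile, CoverageTrack, ModelParams, ParSSite
from .polymer_model import nc_density

__all__ = [
    "read_bedgraph",
    "write_bedgraph",
    "read_bed",
    "normalize_input",
    "estimate_background",
    "make_decay_profile",
    "rescale_overlap",
    "correlate",
    "detect_dips",
    "write_profile_tsv",
    "read_profile_tsv",
]


class BedGraphError(ValueError):
    """Malformed bedGraph input (carries the offending line number)."""


def read_bedgraph(
    path, chrom: str | None = None, start_bp: int | None = None, end_bp: int | None = None
) -> CoverageTrack:
    """Read a bedGraph file into a per-bp :class:`CoverageTrack`.

    Records are 0-based half-open; gaps are filled with 0, overlapping
    records raise. If no window is given, the track spans the file's
    records for the (single) chromosome.
    """
    records = []
    seen_chroms = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise BedGraphError(f"{path}:{ln}: expected 4 fields, got {len(parts)}")
            c, s, e, v = parts[0], parts[1], parts[2], parts[3]
            try:
                s, e, v = int(s), int(e), float(v)
            except ValueError as exc:
                raise BedGraphError(f"{path}:{ln}: {exc}") from None
            if s < 0 or e < 0:
                raise BedGraphError(f"{path}:{ln}: negative coordinate")
            if e <= s:
                raise BedGraphError(f"{path}:{ln}: empty or inverted interval")
            if v < 0:
                raise BedGraphError(f"{path}:{ln}: negative coverage value")
            if chrom is not None and c != chrom:
                continue
            if c not in seen_chroms:
                seen_chroms.append(c)
            records.append((c, s, e, v, ln))

    if chrom is None:
        if len(seen_chroms) > 1:
            raise BedGraphError(
                f"{path}: multiple chromosomes {seen_chroms}; pass chrom= to select one"
            )
        chrom = seen_chroms[0] if seen_chroms else "chr"

    if start_bp is None:
        start_bp = min((r[1] for r in records), default=0)
    if end_bp is None:
        end_bp = max((r[2] for r in records), default=start_bp)

    counts = np.zeros(max(0, end_bp - start_bp))
    filled = np.zeros(counts.size, dtype=bool)
    for _, s, e, v, ln in records:
        lo, hi = max(s, start_bp) - start_bp, min(e, end_bp) - start_bp
        if hi <= lo:
            continue
        if filled[lo:hi].any():
            raise BedGraphError(f"{path}:{ln}: record overlaps an earlier one")
        counts[lo:hi] = v
        filled[lo:hi] = True
    return CoverageTrack(chrom, start_bp, end_bp, counts)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a track as run-length-collapsed bedGraph records."""
    c = track.counts
    with open(path, "w") as fh:
        if c.size == 0:
            return
        boundaries = np.flatnonzero(np.diff(c)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [c.size]])
        for s, e in zip(starts, ends):
            v = c[s]
            vs = f"{int(v)}" if float(v).is_integer() else f"{v:.6g}"
            fh.write(f"{track.chrom}\t{track.start_bp + s}\t{track.start_bp + e}\t{vs}\n")


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Read BED intervals (chrom, start, end, name); name may be empty."""
    out = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >=3 BED fields")
            out.append((parts[0], int(parts[1]), int(parts[2]), parts[3] if len(parts) > 3 else ""))
    return out


def normalize_input(ip: CoverageTrack, inp: CoverageTrack) -> CoverageTrack:
    """Scale the input track to the IP's total read count (IP unchanged)."""
    if (ip.start_bp, ip.end_bp) != (inp.start_bp, inp.end_bp):
        raise ValueError("IP and input tracks must cover the same interval")
    if inp.total <= 0:
        raise ValueError("input track has zero total reads")
    scale = ip.total / inp.total
    return CoverageTrack(inp.chrom, inp.start_bp, inp.end_bp, inp.counts * scale)


def estimate_background(
    ip: CoverageTrack, site: ParSSite, exclusion_bp: float = 25_000.0
) -> float:
    """Background level: median per-bp count outside ± ``exclusion_bp``
    of the site centre (the distal flanks the cluster does not reach)."""
    pos = np.arange(ip.start_bp, ip.end_bp)
    mask = np.abs(pos - site.center_bp) > exclusion_bp
    if not mask.any():
        raise ValueError(
            f"track does not extend beyond the ±{exclusion_bp:.0f} bp exclusion zone"
        )
    return float(np.median(ip.counts[mask]))


def make_decay_profile(
    ip: CoverageTrack,
    site: ParSSite,
    background: float,
    side: str = "right",
    anchor_convention: str = "downstream",
) -> BindingProfile:
    """Background-subtracted decay profile, normalized to 1 at the anchor.

    The anchor is the first bp downstream of the specific repeat block on
    the chosen side (``anchor_convention="downstream"``), or the last bp of
    the repeats themselves (``"last_repeat_bp"`` — the two differ by 1 bp).
    Offsets increase away from parS on either side.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if anchor_convention not in ("downstream", "last_repeat_bp"):
        raise ValueError("anchor_convention must be 'downstream' or 'last_repeat_bp'")

    if side == "right":
        anchor = site.repeat_end_bp if anchor_convention == "downstream" else site.repeat_end_bp - 1
    else:
        anchor = site.repeat_start_bp - 1 if anchor_convention == "downstream" else site.repeat_start_bp
    if not (ip.start_bp <= anchor < ip.end_bp):
        raise ValueError(f"anchor {anchor} outside the track interval")

    sub = np.maximum(0.0, ip.counts - background)
    i_anchor = anchor - ip.start_bp
    ref = sub[i_anchor]
    if ref <= 0:
        raise ValueError("anchor value does not exceed background; cannot normalize")

    if side == "right":
        density = sub[i_anchor:] / ref
    else:
        density = sub[i_anchor::-1] / ref
    offsets = np.arange(density.size, dtype=float)
    return BindingProfile(offsets, density, anchor_bp=anchor, normalized=True)


def rescale_overlap(
    target: BindingProfile, reference: BindingProfile, window_bp: tuple[float, float]
) -> float:
    """Least-squares amplitude factor c minimizing Σ(c·target − reference)²
    over the shared offsets in the window; closed form c = Σtr/Σt²."""
    lo, hi = window_bp
    common, it, ir = np.intersect1d(
        target.offsets_bp, reference.offsets_bp, return_indices=True
    )
    sel = (common >= lo) & (common <= hi)
    if not sel.any():
        raise ValueError("no common offsets in the requested window")
    t = target.density[it[sel]]
    r = reference.density[ir[sel]]
    tt = float(np.dot(t, t))
    if tt == 0.0:
        raise ValueError("target profile is identically zero in the window")
    return float(np.dot(t, r) / tt)


def correlate(x, y) -> float:
    """Pearson correlation, Σ(x−x̄)(y−ȳ) / √(Σ(x−x̄)²·Σ(y−ȳ)²)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt(np.dot(dx, dx) * np.dot(dy, dy))
    if denom == 0.0:
        raise ValueError("zero variance in one of the inputs")
    return float(np.dot(dx, dy) / denom)


def _rolling_mean(v: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return v
    k = np.ones(width)
    return np.convolve(v, k, mode="same") / np.convolve(np.ones_like(v), k, mode="same")


def detect_dips(
    profile: BindingProfile,
    params: ModelParams,
    depth_threshold: float = 0.5,
    min_width_bp: float = 50.0,
    smooth_bp: float = 51.0,
) -> list[tuple[float, float]]:
    """Maximal offset intervals where the smoothed observed/model ratio
    falls below ``depth_threshold`` for at least ``min_width_bp``.

    The model reference is the normalized occupancy law (1 + βs_m)^(-3/2)
    evaluated at each |offset|; dips mark loci where ParB binding is
    locally suppressed (roadblocks). Returns [) intervals in offset bp.
    """
    if not profile.normalized:
        raise ValueError("detect_dips expects an anchor-normalized profile")
    if depth_threshold <= 0:
        return []
    model = nc_density(np.abs(profile.offsets_bp), params) / params.kappa
    step = float(np.median(np.diff(profile.offsets_bp))) if profile.offsets_bp.size > 1 else 1.0
    width = max(1, int(round(smooth_bp / step)))
    ratio = _rolling_mean(profile.density, width) / model
    below = ratio < depth_threshold

    intervals = []
    i = 0
    n = below.size
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            lo = profile.offsets_bp[i]
            hi = profile.offsets_bp[j - 1] + step
            if hi - lo >= min_width_bp:
                intervals.append((float(lo), float(hi)))
            i = j
        else:
            i += 1
    return intervals


def write_profile_tsv(profile: BindingProfile, path) -> None:
    """Two-column TSV (offset_bp, density); header line with the anchor."""
    with open(path, "w") as fh:
        fh.write(f"# anchor_bp={profile.anchor_bp}\tnormalized={int(profile.normalized)}\n")
        fh.write("offset_bp\tdensity\n")
        for o, d in zip(profile.offsets_bp, profile.density):
            fh.write(f"{o:.6g}\t{d:.8g}\n")


def read_profile_tsv(path) -> BindingProfile:
    anchor, normalized = 0, False
    offs, dens = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                for field in line[1:].split():
                    k, _, v = field.partition("=")
                    if k == "anchor_bp":
                        anchor = int(float(v))
                    elif k == "normalized":
                        normalized = bool(int(v))
                continue
            if not line or line.startswith("offset_bp"):
                continue
            o, d = line.split("\t")
            offs.append(float(o))
            dens.append(float(d))
    return BindingProfile(np.array(offs), np.array(dens), anchor_bp=anchor, normalized=normalized)
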