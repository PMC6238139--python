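"""Domain containers shared across the pipeline.

Conventions: genomic intervals are 0-based half-open; lengths along DNA are
in base pairs (bp) unless a name says otherwise; spatial lengths are in
nanometres (nm). The contour conversion between the two is a parameter
(``nm_per_bp``, default 0.34 nm per bp of B-DNA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "ParSSite",
    "BindingProfile",
    "CoverageTrack",
    "ScenarioSpec",
    "FitResult",
    "SimulationConfig",
    "F_PLASMID",
    "VIBRIO_CHR1",
]

#: contour length of one base pair of B-form DNA, nm
NM_PER_BP = 0.34


@dataclass(frozen=True)
class ModelParams:
    """Parameter set of the nucleation-and-caging occupancy model.

    The model pictures ParB as a spherical cluster of Gaussian radial
    profile (width ``sigma_nm``) nucleated at *parS*; flanking DNA, modelled
    as a freely jointed chain of Kuhn segments (``kuhn_bp`` bp each), is
    bound wherever it loops back into the cluster. ``kappa`` is the binding
    probability at the cluster centre — the amplitude of the non-specific
    occupancy profile — and ``n_total`` the total cluster-bound ParB count
    over the one-sided enriched length ``enriched_length_bp``.
    """

    sigma_nm: float = 75.0
    kuhn_bp: float = 10.0
    kappa: float = 0.41
    n_total: float = 360.0
    enriched_length_bp: float = 15_000.0
    nm_per_bp: float = NM_PER_BP

    def __post_init__(self) -> None:
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError(f"kappa must be in [0, 1], got {self.kappa}")
        if self.sigma_nm <= 0:
            raise ValueError("sigma_nm must be positive")
        if self.kuhn_bp < 1:
            raise ValueError("kuhn_bp must be >= 1")
        if self.enriched_length_bp <= 0:
            raise ValueError("enriched_length_bp must be positive")
        if self.n_total < 0:
            raise ValueError("n_total must be >= 0")
        if self.nm_per_bp <= 0:
            raise ValueError("nm_per_bp must be positive")

    @property
    def kuhn_nm(self) -> float:
        """Kuhn length in nm."""
        return self.kuhn_bp * self.nm_per_bp

    @property
    def n_monomers(self) -> int:
        """Number of Kuhn monomers in the enriched length."""
        return int(round(self.enriched_length_bp / self.kuhn_bp))

    @property
    def beta(self) -> float:
        """Decay rate a²/(3σ²) per monomer of the occupancy law."""
        return self.kuhn_nm**2 / (3.0 * self.sigma_nm**2)

    def replace(self, **kwargs) -> "ModelParams":
        from dataclasses import replace

        return replace(self, **kwargs)


#: F-plasmid parameter set (E. coli host): sigma from superresolution
#: microscopy, kappa and Kuhn length from the ChIP-seq fit.
F_PLASMID = ModelParams(
    sigma_nm=75.0, kuhn_bp=10.0, kappa=0.41, n_total=360.0, enriched_length_bp=15_000.0
)

#: V. cholerae chromosome 1 preset (three parS, semi-quantitative).
VIBRIO_CHR1 = ModelParams(
    sigma_nm=25.0, kuhn_bp=16.0, kappa=0.15, n_total=50.0, enriched_length_bp=32_000.0
)


@dataclass(frozen=True)
class ParSSite:
    """A nucleation site: the genomic interval of specific binding repeats,
    the coordinate of the cluster centre, and the relative occupancy weight
    of the always-bound specific complex (1.0 = always occupied)."""

    repeat_start_bp: int
    repeat_end_bp: int
    center_bp: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.repeat_start_bp >= self.repeat_end_bp:
            raise ValueError("repeat interval must be non-empty (start < end)")
        if not (0.0 < self.weight <= 1.0):
            raise ValueError(f"weight must be in (0, 1], got {self.weight}")
        # centre may sit inside or immediately adjacent to the repeat block
        if not (self.repeat_start_bp - 1 <= self.center_bp <= self.repeat_end_bp):
            raise ValueError("center_bp must lie within or adjacent to the repeats")

    @property
    def repeat_length_bp(self) -> int:
        return self.repeat_end_bp - self.repeat_start_bp


@dataclass
class BindingProfile:
    """Normalized ParB density versus signed genomic offset from an anchor.

    ``offsets_bp`` are signed distances from ``anchor_bp`` (strictly
    increasing); ``density`` is the dimensionless occupancy. If
    ``normalized`` is set, the density at the offset closest to 0 is 1.
    ``se`` optionally carries a Monte-Carlo standard error per offset.
    """

    offsets_bp: np.ndarray
    density: np.ndarray
    anchor_bp: int = 0
    normalized: bool = False
    se: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.offsets_bp = np.asarray(self.offsets_bp, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.offsets_bp.shape != self.density.shape:
            raise ValueError("offsets_bp and density must have the same shape")
        if self.offsets_bp.size >= 2 and not np.all(np.diff(self.offsets_bp) > 0):
            raise ValueError("offsets_bp must be strictly increasing")
        if np.any(self.density < -1e-12):
            raise ValueError("density must be non-negative")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.density.shape:
                raise ValueError("se must match density shape")

    def value_at(self, offset_bp: float) -> float:
        """Density at the grid point closest to ``offset_bp``."""
        i = int(np.argmin(np.abs(self.offsets_bp - offset_bp)))
        return float(self.density[i])

    def window(self, lo_bp: float, hi_bp: float) -> "BindingProfile":
        """Sub-profile with offsets in [lo_bp, hi_bp]."""
        m = (self.offsets_bp >= lo_bp) & (self.offsets_bp <= hi_bp)
        return BindingProfile(
            self.offsets_bp[m],
            self.density[m],
            anchor_bp=self.anchor_bp,
            normalized=self.normalized,
            se=None if self.se is None else self.se[m],
        )


@dataclass
class CoverageTrack:
    """Per-bp read counts over a genomic interval (IP or input sample)."""

    chrom: str
    start_bp: int
    end_bp: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.end_bp - self.start_bp != self.counts.size:
            raise ValueError("counts length must equal end_bp - start_bp")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def __len__(self) -> int:
        return self.counts.size


@dataclass(frozen=True)
class ScenarioSpec:
    """Family of cluster-size scenarios under ParB-amount variation.

    ``constant_size``: the cluster radius σ is fixed and the amplitude
    scales with the ParB count m — profiles collapse after amplitude
    rescaling. ``constant_concentration``: compact clusters of fixed
    density, so σ grows like m^(1/3) — profile shapes differ.
    """

    mode: str
    reference_m: float
    ratios: Sequence[float] = field(default_factory=lambda: (0.4, 1.0, 16.0, 28.0))

    MODES = ("constant_size", "constant_concentration")

    def __post_init__(self) -> None:
        if self.mode not in self.MODES:
            raise ValueError(f"mode must be one of {self.MODES}, got {self.mode!r}")
        if self.reference_m <= 0:
            raise ValueError("reference_m must be positive")
        if any(r <= 0 for r in self.ratios):
            raise ValueError("ratios must be positive")


@dataclass
class FitResult:
    """Result of fitting A0·(1 + A1·ℓ(s))^(-3/2) to a decay profile.

    ``a0`` is dimensionless (identified with κ); ``a1_per_nm`` has units
    nm⁻¹ and yields the Kuhn length as a = 3σ²·A1. ``n_total`` is the
    cluster-bound ParB count implied by κ over the enriched length.
    """

    a0: float
    a1_per_nm: float
    kappa: float
    kuhn_nm: float
    kuhn_bp: float
    n_total: float
    window_bp: tuple[float, float]
    sse: float
    sigma_nm: float
    nm_per_bp: float = NM_PER_BP

    def __post_init__(self) -> None:
        if not (0.0 < self.a0 <= 1.0):
            raise ValueError(f"A0 must be in (0, 1], got {self.a0}")
        if self.a1_per_nm <= 0:
            raise ValueError("A1 must be positive")
        if self.n_total < 0:
            raise ValueError("n_total must be >= 0")

    def to_dict(self) -> dict:
        return {
            "A0": self.a0,
            "A1_per_nm": self.a1_per_nm,
            "kappa": self.kappa,
            "kuhn_nm": self.kuhn_nm,
            "kuhn_bp": self.kuhn_bp,
            "n_total": self.n_total,
            "window_bp": list(self.window_bp),
            "sse": self.sse,
            "sigma_nm": self.sigma_nm,
            "nm_per_bp": self.nm_per_bp,
        }


@dataclass(frozen=True)
class SimulationConfig:
    """Monte-Carlo run configuration for the freely-jointed-chain sampler."""

    n_monomers: int = 1500
    n_conformations: int = 20_000
    seed: int = 0
    fragment_bp: float = 0.0
    exact_probability: bool = True

    def __post_init__(self) -> None:
        if self.n_monomers < 2:
            raise ValueError("n_monomers must be >= 2")
        if self.n_conformations < 1:
            raise ValueError("n_conformations must be >= 1")
        if self.fragment_bp < 0:
            raise ValueError("fragment_bp must be >= 0")
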