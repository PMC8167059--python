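"""False-discovery-rate confidence maps.

The background (null) intensity distribution is estimated from four small
cubes placed outside the particle volume, near the box faces on the central
x and y axes.  Every voxel is then tested against that Gaussian null with a
right-tailed test (molecular signal is positive density in a sharpened map),
the per-voxel p-values are adjusted for multiplicity with a step-up FDR
procedure — Benjamini–Yekutieli by default, which remains valid under the
strong spatial dependence of reconstructed voxels — and the confidence is
1 − adjusted p.  A confidence of 0.99 therefore marks the 1% FDR contour:
among voxels at or above it, at most 1% are expected to be background.

Masked or solvent-flattened maps have no background left to estimate and are
rejected (:class:`~fdrval.errors.DegenerateNoiseError`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import ConfigurationError, DegenerateNoiseError
from .map_io import DensityMap

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseRegionSpec",
    "NoiseEstimate",
    "ConfidenceMap",
    "NoiseDiagnostics",
    "default_noise_regions",
    "check_noise_regions",
    "estimate_noise",
    "voxel_p_values",
    "fdr_adjust",
    "confidence_map",
]

#: smallest representable positive p-value; sf() underflows to 0 for z >~ 39
_P_FLOOR = np.finfo(np.float64).tiny


@dataclass(frozen=True)
class NoiseRegionSpec:
    """Cubic background regions used for noise estimation.

    ``cube_centers`` are integer voxel index triples (X, Y, Z order);
    ``edge_voxels`` is the odd cube edge length (≥ 3).  Cubes must lie
    entirely inside the grid and be pairwise disjoint.
    """

    cube_centers: tuple[tuple[int, int, int], ...]
    edge_voxels: int

    def __post_init__(self) -> None:
        if self.edge_voxels < 3 or self.edge_voxels % 2 == 0:
            raise ConfigurationError(
                f"edge_voxels must be an odd integer >= 3, got {self.edge_voxels}"
            )
        if not self.cube_centers:
            raise ConfigurationError("at least one noise cube is required")

    @property
    def n_voxels(self) -> int:
        return self.edge_voxels**3 * len(self.cube_centers)

    def cube_slices(self) -> list[tuple[slice, slice, slice]]:
        h = self.edge_voxels // 2
        return [
            tuple(slice(c - h, c + h + 1) for c in center)  # type: ignore[return-value]
            for center in self.cube_centers
        ]

    def validate(self, dims) -> None:
        """Raise ConfigurationError if any cube leaves the grid or two overlap."""
        dims = np.asarray(dims)
        h = self.edge_voxels // 2
        for center in self.cube_centers:
            c = np.asarray(center)
            if np.any(c - h < 0) or np.any(c + h > dims - 1):
                raise ConfigurationError(
                    f"noise cube centered at {center} (edge {self.edge_voxels}) "
                    f"does not fit inside grid of dims {tuple(dims)}"
                )
        for i, a in enumerate(self.cube_centers):
            for b in self.cube_centers[i + 1 :]:
                if all(abs(ai - bi) < self.edge_voxels for ai, bi in zip(a, b)):
                    raise ConfigurationError(f"noise cubes at {a} and {b} overlap")


@dataclass(frozen=True)
class NoiseEstimate:
    """Pooled Gaussian background parameters (map-value units)."""

    mean: float
    sd: float
    n_voxels: int
    regions: NoiseRegionSpec


@dataclass
class ConfidenceMap(DensityMap):
    """A density map whose values are confidences 1 − q ∈ [0, 1], with q the
    FDR-adjusted p-value of the voxel under the background null."""

    fdr_method: str = "by"
    noise: NoiseEstimate | None = field(default=None, compare=False)


def default_edge_voxels(dims) -> int:
    """Largest odd integer ≤ 0.125 × min grid dimension, with floor 5."""
    e = int(math.floor(0.125 * min(dims)))
    if e % 2 == 0:
        e -= 1
    return max(e, 5)


def default_noise_regions(
    dmap: DensityMap,
    edge_voxels: int | None = None,
    guard_fraction: float = 0.35,
) -> NoiseRegionSpec:
    """Four noise cubes at the −x, +x, −y, +y face midpoints.

    Each cube is pushed against the box face and must lie entirely outside a
    central guard sphere of radius ``guard_fraction × min box extent`` (Å),
    assumed to contain the particle.  Raises
    :class:`~fdrval.errors.ConfigurationError` when the box is too small to
    host cubes of the requested edge outside the guard sphere.
    """
    if not 0.0 <= guard_fraction <= 0.5:
        raise ConfigurationError(f"guard_fraction must be in [0, 0.5], got {guard_fraction}")
    dims = np.asarray(dmap.dims)
    if edge_voxels is None:
        edge_voxels = default_edge_voxels(dims)
    if edge_voxels < 3 or edge_voxels % 2 == 0:
        raise ConfigurationError(f"edge_voxels must be an odd integer >= 3, got {edge_voxels}")
    h = edge_voxels // 2
    if np.any(dims < edge_voxels):
        raise ConfigurationError(
            f"grid dims {tuple(dims)} cannot host noise cubes of edge {edge_voxels}"
        )
    mid = dims // 2
    centers = [
        (h, int(mid[1]), int(mid[2])),
        (int(dims[0]) - 1 - h, int(mid[1]), int(mid[2])),
        (int(mid[0]), h, int(mid[2])),
        (int(mid[0]), int(dims[1]) - 1 - h, int(mid[2])),
    ]
    spec = NoiseRegionSpec(tuple(centers), edge_voxels)
    spec.validate(dims)

    guard_radius = guard_fraction * float(np.min(dims * dmap.voxel_size))
    box_center = dmap.origin + (dims - 1) / 2.0 * dmap.voxel_size
    for center, slc in zip(spec.cube_centers, spec.cube_slices()):
        lo = dmap.origin + np.array([s.start for s in slc]) * dmap.voxel_size
        hi = dmap.origin + np.array([s.stop - 1 for s in slc]) * dmap.voxel_size
        nearest = np.clip(box_center, lo, hi)
        if np.linalg.norm(nearest - box_center) < guard_radius:
            raise ConfigurationError(
                f"noise cube at {center} (edge {edge_voxels}) intrudes into the "
                f"guard sphere of radius {guard_radius:.1f} Å; the box is too "
                f"small for this cube size — reduce edge_voxels or guard_fraction"
            )
    return spec


@dataclass(frozen=True)
class NoiseDiagnostics:
    """Per-cube summary from :func:`check_noise_regions` (diagnostics only)."""

    cube_means: tuple[float, ...]
    cube_sds: tuple[float, ...]
    n_per_cube: int
    flagged: tuple[int, ...]  # indices of possibly signal-contaminated cubes
    degenerate: tuple[int, ...]  # indices of zero-spread cubes

    @property
    def ok(self) -> bool:
        return not self.flagged and not self.degenerate


def check_noise_regions(
    dmap: DensityMap, regions: NoiseRegionSpec, k: float = 5.0
) -> NoiseDiagnostics:
    """Screen noise cubes for signal contamination.

    A cube is flagged when its mean exceeds the pooled mean of the *other*
    cubes by more than ``k`` standard errors (pooled-others sd / √n_cube).
    Cubes with zero spread are reported as degenerate.  Never mutates data.
    """
    regions.validate(dmap.dims)
    blocks = [dmap.values[slc].ravel() for slc in regions.cube_slices()]
    means = [float(np.mean(b)) for b in blocks]
    sds = [float(np.std(b, ddof=1)) if b.size > 1 else 0.0 for b in blocks]
    n_cube = regions.edge_voxels**3
    flagged, degenerate = [], []
    for i, b in enumerate(blocks):
        if sds[i] == 0.0:
            degenerate.append(i)
        if len(blocks) < 2:
            continue
        others = np.concatenate([blocks[j] for j in range(len(blocks)) if j != i])
        others_sd = float(np.std(others, ddof=1))
        if others_sd == 0.0:
            continue
        if means[i] - float(np.mean(others)) > k * others_sd / math.sqrt(n_cube):
            flagged.append(i)
    diag = NoiseDiagnostics(tuple(means), tuple(sds), n_cube, tuple(flagged), tuple(degenerate))
    if not diag.ok:
        logger.warning(
            "noise-region check: flagged cubes %s, degenerate cubes %s",
            diag.flagged,
            diag.degenerate,
        )
    return diag


def estimate_noise(dmap: DensityMap, regions: NoiseRegionSpec | None = None) -> NoiseEstimate:
    """Pooled mean and sample sd of the background over all cube voxels."""
    if regions is None:
        regions = default_noise_regions(dmap)
    regions.validate(dmap.dims)
    pooled = np.concatenate([dmap.values[slc].ravel() for slc in regions.cube_slices()])
    sd = float(np.std(pooled, ddof=1))
    if sd == 0.0:
        raise DegenerateNoiseError(
            "background spread is zero — the noise cubes contain constant values. "
            "Masked or solvent-flattened maps have no background to estimate and "
            "are unsuitable; supply a sharpened, unmasked map."
        )
    return NoiseEstimate(mean=float(np.mean(pooled)), sd=sd, n_voxels=pooled.size, regions=regions)


def voxel_p_values(dmap: DensityMap, noise: NoiseEstimate) -> np.ndarray:
    """Right-tailed Gaussian p-value per voxel: p = 1 − Φ((v − μ)/σ)."""
    if noise.sd <= 0:
        raise DegenerateNoiseError("noise sd must be positive")
    p = norm.sf((dmap.values - noise.mean) / noise.sd)
    return np.clip(p, _P_FLOOR, 1.0)


def fdr_adjust(p_values, method: str = "by") -> np.ndarray:
    """Step-up FDR-adjusted q-values, in the input order.

    ``method="bh"`` is Benjamini–Hochberg; ``method="by"`` (default)
    additionally multiplies by the harmonic correction c(m) = Σ_{i≤m} 1/i,
    which keeps the procedure valid under arbitrary dependence between
    tests — the appropriate choice for spatially correlated voxels.
    Monotonicity is enforced by a running minimum from the largest p
    downwards; q is clipped to ≤ 1.
    """
    p = np.asarray(p_values, dtype=np.float64).ravel()
    if p.size == 0:
        raise ValueError("fdr_adjust requires a non-empty input")
    if np.any(p <= 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    method = method.lower()
    if method not in ("by", "bh"):
        raise ValueError(f"unknown FDR method {method!r}; use 'by' or 'bh'")
    m = p.size
    c = float(np.sum(1.0 / np.arange(1, m + 1))) if method == "by" else 1.0
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1, dtype=np.float64)
    q_sorted = p[order] * m * c / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    np.clip(q_sorted, None, 1.0, out=q_sorted)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def confidence_map(
    dmap: DensityMap,
    regions: NoiseRegionSpec | None = None,
    method: str = "by",
) -> ConfidenceMap:
    """Compute the confidence map c = 1 − q on the input's geometry."""
    if regions is None:
        regions = default_noise_regions(dmap)
    noise = estimate_noise(dmap, regions)
    logger.info(
        "noise estimate: mean=%.6g sd=%.6g over %d voxels (%d cubes, edge %d); FDR method %s",
        noise.mean,
        noise.sd,
        noise.n_voxels,
        len(regions.cube_centers),
        regions.edge_voxels,
        method.upper(),
    )
    p = voxel_p_values(dmap, noise)
    q = fdr_adjust(p.ravel(), method=method).reshape(dmap.dims)
    return ConfidenceMap(
        values=1.0 - q,
        voxel_size=dmap.voxel_size,
        origin=dmap.origin,
        axis_order=dmap.axis_order,
        label=dmap.label,
        fdr_method=method.lower(),
        noise=noise,
    )


def confidence_sidecar(cmap: ConfidenceMap) -> dict:
    """Provenance record (JSON-serialisable) for a computed confidence map."""
    noise = cmap.noise
    return {
        "fdr_method": cmap.fdr_method,
        "noise_mean": noise.mean if noise else None,
        "noise_sd": noise.sd if noise else None,
        "noise_n_voxels": noise.n_voxels if noise else None,
        "noise_cube_edge": noise.regions.edge_voxels if noise else None,
        "noise_cube_centers": [list(c) for c in noise.regions.cube_centers] if noise else None,
        "dims": list(cmap.dims),
        "voxel_size": [float(v) for v in cmap.voxel_size],
        "origin": [float(v) for v in cmap.origin],
    }
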