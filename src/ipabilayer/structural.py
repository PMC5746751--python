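"""Structural observables of IPA bilayers.

Covers the per-system structural characterization: area per IPA complex
(mean lateral box area divided by molecules per leaflet), transverse density
profiles of the head-group heteroatoms relative to the bilayer midplane,
alkyl-chain tilt angles (director = first to second-last chain carbon, angle
folded against the leaflet normal into [0, 90] deg), deuterium order
parameters S_CD with united-atom hydrogen reconstruction, per-dihedral
gauche fractions (torsion in (-120, 120) deg), and middle-segment averages
over carbons 2..min(m, n).

S_CD = (1/2) <3 cos^2(alpha) - 1>, with alpha the angle between the C-H bond
vector and the bilayer normal.  United-atom topologies carry no hydrogens, so
the two methylene H positions are reconstructed from the carbon neighbors by
ideal tetrahedral geometry: the H pair lies in the plane perpendicular to the
C_{i-1} -> C_{i+1} axis, straddling the backbone bisector with an H-C-H angle
of 109.47 deg.  C1 and the terminal methyl lack two carbon neighbors and are
excluded, so the profile runs over carbons 2..L-1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model import IPAComposition, Trajectory, bilayer_midplane

H_C_H_ANGLE = 109.47  # deg, ideal tetrahedral


# ---------------------------------------------------------------------------
# area per IPA
# ---------------------------------------------------------------------------


@dataclass
class AreaSeries:
    """Per-frame lateral box areas (nm^2) and the per-leaflet molecule count."""

    values: np.ndarray
    n_per_leaflet: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and np.any(self.values <= 0):
            raise ValueError("lateral areas must be positive")

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def variance(self) -> float:
        """Population (1/M) variance, nm^4."""
        return float(self.values.var())


def area_series(traj: Trajectory) -> AreaSeries:
    return AreaSeries(traj.lateral_areas(), traj.n_per_leaflet)


def area_per_ipa(series: AreaSeries) -> float:
    """Mean lateral area divided by molecules per leaflet, nm^2."""
    if series.n_per_leaflet <= 0:
        raise ValueError("n_per_leaflet must be positive")
    if series.values.size == 0:
        raise ValueError("empty area series")
    return series.mean / series.n_per_leaflet


# ---------------------------------------------------------------------------
# transverse density profiles
# ---------------------------------------------------------------------------


@dataclass
class DensityProfile:
    """Midplane-relative z histograms of head-group species.

    ``densities[s]`` integrates (sum * bin_width) to the per-frame atom count
    of species ``s``.
    """

    bin_centers: np.ndarray
    densities: dict[str, np.ndarray]
    bin_width: float
    n_frames: int

    def peak_position(self, species: str, half: str) -> float:
        """z of the maximum-density bin in the upper (z>0) or lower half."""
        dens = self.densities[species]
        mask = self.bin_centers > 0 if half == "upper" else self.bin_centers < 0
        if not np.any(mask):
            raise ValueError(f"no bins in the {half} half-profile")
        sub = np.where(mask, dens, -np.inf)
        return float(self.bin_centers[np.argmax(sub)])


_SPECIES_HEAD = {"N": "cation", "S": "anion"}


def density_profile(
    traj: Trajectory,
    species: Sequence[str] = ("N", "S"),
    bin_width: float = 0.05,
) -> DensityProfile:
    """Histogram head-group z positions relative to the per-frame midplane."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(traj) < 1:
        raise ValueError("trajectory has no frames")

    rel = {}
    for sp in species:
        if sp not in _SPECIES_HEAD:
            raise ValueError(f"unknown species {sp!r}; expected 'N' or 'S'")
        idx = traj.head_indices(_SPECIES_HEAD[sp])
        z = traj.coordinates[:, idx, 2]
        mids = np.array([bilayer_midplane(traj.frame(i), traj) for i in range(len(traj))])
        rel[sp] = (z - mids[:, None]).ravel()

    zmax = max(np.abs(v).max() for v in rel.values()) + bin_width
    n_half = math.ceil(zmax / bin_width)
    edges = np.arange(-n_half, n_half + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    densities = {
        sp: np.histogram(v, bins=edges)[0] / (len(traj) * bin_width)
        for sp, v in rel.items()
    }
    return DensityProfile(centers, densities, bin_width, len(traj))


def head_alignment_offset(profile: DensityProfile) -> tuple[float, float]:
    """Signed N-minus-S peak offset per leaflet, averaged over leaflets.

    Returns (offset_nm, uncertainty_nm); the uncertainty is one bin width
    (peak positions are argmax bins, no smoothing).  Zero offset is the
    head-alignment property: nitrogen and sulfur planes at the same height.
    """
    for sp in ("N", "S"):
        if sp not in profile.densities:
            raise ValueError(f"profile lacks species {sp!r}")
    upper = profile.peak_position("N", "upper") - profile.peak_position("S", "upper")
    lower = profile.peak_position("S", "lower") - profile.peak_position("N", "lower")
    if profile.n_frames < 2:
        warnings.warn(
            "single-frame profile: peak offset carries at least one bin width "
            "of uncertainty"
        )
    return 0.5 * (upper + lower), profile.bin_width


# ---------------------------------------------------------------------------
# tilt angles
# ---------------------------------------------------------------------------


@dataclass
class TiltSamples:
    """Pooled tilt angles (degrees, [0, 90]) keyed by chain type."""

    samples: dict[str, np.ndarray]

    def pooled(self) -> np.ndarray:
        return np.concatenate(list(self.samples.values()))

    def __getitem__(self, chain_type: str) -> np.ndarray:
        return self.samples[chain_type]


@dataclass
class TiltDistribution:
    """Probability-normalized tilt histogram (sums to 1 over bins)."""

    bin_centers: np.ndarray
    probabilities: np.ndarray
    bin_width: float


def chain_directors(traj: Trajectory, chain_type: str) -> np.ndarray:
    """(F, M, 3) director vectors, first to second-last chain carbon."""
    idx = traj.chain_indices(chain_type)
    if idx.shape[1] < 3:
        raise ValueError("chain must have at least 3 carbons for a director")
    return traj.coordinates[:, idx[:, -2], :] - traj.coordinates[:, idx[:, 0], :]


def fold_tilt(directors: np.ndarray) -> np.ndarray:
    """Angle (deg) between directors and the bilayer normal, folded to [0, 90].

    Folding (taking |d_z|) applies the leaflet sign convention: a chain along
    the outward normal of either leaflet measures 0 deg.
    """
    norm = np.linalg.norm(directors, axis=-1)
    cosang = np.abs(directors[..., 2]) / norm
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def tilt_angles(traj: Trajectory, chain_type: str | None = None) -> TiltSamples:
    """Per-molecule per-frame tilt angles, pooled over frames and molecules."""
    types = ("cation", "anion") if chain_type is None else (chain_type,)
    return TiltSamples(
        {t: fold_tilt(chain_directors(traj, t)).ravel() for t in types}
    )


def tilt_distribution(
    samples: np.ndarray | TiltSamples, bin_width: float = 1.0
) -> TiltDistribution:
    """Normalized tilt-angle histogram over [0, 90] degrees."""
    if isinstance(samples, TiltSamples):
        samples = samples.pooled()
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("no tilt samples")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = math.ceil(90.0 / bin_width)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(np.clip(samples, 0.0, edges[-1] - 1e-12), bins=edges)
    return TiltDistribution(
        0.5 * (edges[:-1] + edges[1:]), counts / counts.sum(), bin_width
    )


# ---------------------------------------------------------------------------
# deuterium order parameters
# ---------------------------------------------------------------------------


@dataclass
class ScdProfile:
    """Signed S_CD per carbon index (2..L-1) for one chain type."""

    carbons: np.ndarray  # 1-based carbon indices
    values: np.ndarray
    counts: np.ndarray  # C-H samples per carbon

    def as_mapping(self) -> dict[int, float]:
        return {int(c): float(v) for c, v in zip(self.carbons, self.values)}


def scd_from_chain_coords(chain_coords: np.ndarray, normal_axis: int = 2) -> ScdProfile:
    """S_CD per methylene from (..., L, 3) united-atom chain coordinates.

    Reconstructs both methylene hydrogens per interior carbon and averages
    (3 cos^2(alpha) - 1)/2 over hydrogens and samples.
    """
    chain_coords = np.asarray(chain_coords, dtype=float)
    L = chain_coords.shape[-2]
    if L < 3:
        raise ValueError("S_CD needs chains of at least 3 carbons")
    flat = chain_coords.reshape(-1, L, 3)

    prev_c = flat[:, :-2]  # C_{i-1}
    this_c = flat[:, 1:-1]  # C_i
    next_c = flat[:, 2:]  # C_{i+1}

    u = next_c - prev_c
    u /= np.linalg.norm(u, axis=-1, keepdims=True)
    a = prev_c - this_c
    b = next_c - this_c
    v = -(a / np.linalg.norm(a, axis=-1, keepdims=True)
          + b / np.linalg.norm(b, axis=-1, keepdims=True))
    v -= np.einsum("sij,sij->si", v, u)[..., None] * u
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    w = np.cross(u, v)

    half = math.radians(H_C_H_ANGLE / 2.0)
    h1 = math.cos(half) * v + math.sin(half) * w
    h2 = math.cos(half) * v - math.sin(half) * w
    cos2 = np.stack([h1[..., normal_axis] ** 2, h2[..., normal_axis] ** 2])
    scd = 0.5 * (3.0 * cos2 - 1.0)  # (2, S, L-2)
    values = scd.mean(axis=(0, 1))
    counts = np.full(L - 2, 2 * flat.shape[0])
    return ScdProfile(np.arange(2, L), values, counts)


def scd_profile(traj: Trajectory, chain_type: str) -> ScdProfile:
    """S_CD profile for one chain type, averaged over molecules and frames."""
    idx = traj.chain_indices(chain_type)
    chain_coords = traj.coordinates[:, idx, :]  # (F, M, L, 3)
    return scd_from_chain_coords(chain_coords)


# ---------------------------------------------------------------------------
# gauche fractions
# ---------------------------------------------------------------------------


@dataclass
class DihedralStats:
    """Per-dihedral gauche fractions for one chain type.

    A dihedral over carbons (i, i+1, i+2, i+3) is labeled by its first
    carbon i, so labels run 1..L-3.
    """

    carbons: np.ndarray
    fractions: np.ndarray
    counts: np.ndarray

    @property
    def overall(self) -> float:
        return float(
            np.average(self.fractions, weights=self.counts)
        ) if self.fractions.size else math.nan

    def as_mapping(self) -> dict[int, float]:
        return {int(c): float(f) for c, f in zip(self.carbons, self.fractions)}


def dihedral_angles(chain_coords: np.ndarray) -> np.ndarray:
    """Signed torsion angles (deg, IUPAC: trans=180) for (..., L, 3) chains."""
    chain_coords = np.asarray(chain_coords, dtype=float)
    b1 = chain_coords[..., 1:-2, :] - chain_coords[..., 0:-3, :]
    b2 = chain_coords[..., 2:-1, :] - chain_coords[..., 1:-2, :]
    b3 = chain_coords[..., 3:, :] - chain_coords[..., 2:-1, :]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", np.cross(n1, n2), b2n)
    return np.degrees(np.arctan2(y, x))


def is_gauche(torsions_deg: np.ndarray) -> np.ndarray:
    """Gauche iff torsion lies strictly inside (-120, 120) deg."""
    return np.abs(torsions_deg) < 120.0


def gauche_fractions(traj: Trajectory, chain_type: str) -> DihedralStats:
    """Fraction of gauche conformers per rotatable dihedral along the chain."""
    idx = traj.chain_indices(chain_type)
    L = idx.shape[1]
    if L < 4:
        warnings.warn(f"{chain_type} chain too short for dihedrals (L={L})")
        return DihedralStats(np.array([], int), np.array([]), np.array([], int))
    chain_coords = traj.coordinates[:, idx, :]
    g = is_gauche(dihedral_angles(chain_coords))  # (F, M, L-3)
    frac = g.mean(axis=(0, 1))
    counts = np.full(L - 3, g.shape[0] * g.shape[1])
    return DihedralStats(np.arange(1, L - 2), frac, counts)


# ---------------------------------------------------------------------------
# middle-segment averages
# ---------------------------------------------------------------------------


def middle_segment_average(
    per_carbon: Mapping[str, Mapping[int, float]] | Mapping[int, float],
    composition: IPAComposition,
) -> float:
    """Average a per-carbon profile over the middle segment, carbons 2..min(m, n).

    The upper bound is capped at the largest carbon index for which the value
    is computable on each chain (L-1 for S_CD, L-3 for dihedral labels).  For
    a two-chain input the per-chain window means are averaged.
    """
    lo, hi = 2, min(composition.m, composition.n)

    def window_mean(mapping: Mapping[int, float]) -> float:
        if not mapping:
            raise ValueError("empty per-carbon profile")
        cap = min(hi, max(mapping))
        vals = [mapping[c] for c in range(lo, cap + 1) if c in mapping]
        if not vals:
            raise ValueError(
                f"middle segment {lo}..{cap} not covered by the profile"
            )
        return float(np.mean(vals))

    if not per_carbon:
        raise ValueError("empty per-carbon profile")
    first = next(iter(per_carbon.values()))
    if isinstance(first, Mapping):
        return float(np.mean([window_mean(v) for v in per_carbon.values()]))
    return window_mean(per_carbon)  # type: ignore[arg-type]
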