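"""Mechanical moduli of IPA bilayers from equilibrium fluctuations.

Three moduli are computed, all from unperturbed trajectories:

* the area expansion modulus ``K_A = k_B T <A> / (N <dA^2>)`` from the
  lateral-area fluctuations (linear response), reported in mN/m;
* the molecular tilt modulus ``chi``: the tilt free energy
  ``F(theta) = -RT ln[P(theta)/sin(theta)]`` is obtained by Boltzmann
  inversion of the tilt-angle distribution (sin(theta) is the Jacobian of
  the polar angle) and fit with a quadratic
  ``F(theta0) + chi/2 (theta - theta0)^2`` near its minimum; reported in
  J/mol/deg^2;
* per-pair-type splay moduli ``chi_ij`` (cation-cation, anion-anion, mixed)
  from the same inversion + quadratic-fit machinery applied to the splay
  angle between director vectors of neighboring same-leaflet chains, and the
  effective bending rigidity ``KC_eff`` as their phi-weighted harmonic mean
  (phi_ij = splay sample counts), both reported in k_B T.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    DEFAULT_TEMPERATURE,
    ka_to_mN_per_m,
    kbt,
    molar_deg2_to_kbt_rad2,
    rt,
)
from .model import Trajectory, assign_leaflets
from .structural import (
    AreaSeries,
    TiltDistribution,
    chain_directors,
    tilt_distribution,
)

PAIR_TYPES = ("++", "--", "+-")


@dataclass
class PMFProfile:
    """Free energy (J/mol) over occupied angle bins, shifted so min F = 0."""

    bin_centers: np.ndarray  # degrees
    free_energy: np.ndarray  # J/mol
    bin_width: float

    def __post_init__(self):
        if self.free_energy.size:
            self.free_energy = self.free_energy - self.free_energy.min()


@dataclass
class QuadraticFit:
    """Diagnostics of the quadratic PMF fit."""

    chi: float  # curvature, J/mol/deg^2
    theta0: float  # minimizer, degrees
    window: tuple[float, float]
    n_points: int
    r_squared: float


@dataclass
class SplayResult:
    """Per-pair-type splay statistics and moduli."""

    chi: dict[str, float]  # k_B T units
    phi: dict[str, int]  # sample counts
    fits: dict[str, QuadraticFit] = field(default_factory=dict)


@dataclass
class MechanicalResult:
    ka_mN_per_m: float
    chi_tilt: float  # pooled, J/mol/deg^2
    chi_tilt_by_chain: dict[str, float]
    theta0: float  # degrees
    splay: SplayResult | None
    kc_eff_kbt: float | None
    tilt_fit: QuadraticFit | None = None


# ---------------------------------------------------------------------------
# area expansion modulus
# ---------------------------------------------------------------------------


def area_expansion_modulus(
    series: AreaSeries, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """K_A = k_B T <A> / (N <dA^2>), in mN/m.

    Uses the population (1/M) variance of the lateral-area series.
    """
    if series.values.size < 2:
        raise ValueError("need at least 2 frames for area fluctuations")
    var = series.variance
    if var == 0.0:
        raise ZeroDivisionError(
            "area series has zero variance: modulus is infinite "
            "(constant-area input)"
        )
    ka_J_per_nm2 = kbt(temperature) * series.mean / (series.n_per_leaflet * var)
    return ka_to_mN_per_m(ka_J_per_nm2)


# ---------------------------------------------------------------------------
# Boltzmann inversion and quadratic fitting
# ---------------------------------------------------------------------------


def boltzmann_invert(
    distribution: TiltDistribution,
    temperature: float = DEFAULT_TEMPERATURE,
    jacobian: str = "divide",
) -> PMFProfile:
    """F(theta) = -RT ln(P(theta)/sin(theta)) over occupied bins, min-shifted.

    ``jacobian="divide"`` removes the polar-angle phase-space factor so that
    uniformly oriented directors give a flat profile; ``"multiply"`` is kept
    as a configurable alternative reading.
    """
    if jacobian not in ("divide", "multiply"):
        raise ValueError("jacobian must be 'divide' or 'multiply'")
    p = np.asarray(distribution.probabilities, dtype=float)
    occupied = p > 0
    if not np.any(occupied):
        raise ValueError("empty histogram: nothing to invert")
    theta = distribution.bin_centers[occupied]
    sin_t = np.sin(np.radians(theta))
    sin_t = np.where(sin_t <= 0, np.nan, sin_t)
    ratio = p[occupied] / sin_t if jacobian == "divide" else p[occupied] * sin_t
    keep = np.isfinite(ratio)
    F = -rt(temperature) * np.log(ratio[keep])
    return PMFProfile(theta[keep], F, distribution.bin_width)


def reconstruct_distribution(
    pmf: PMFProfile, temperature: float = DEFAULT_TEMPERATURE
) -> np.ndarray:
    """Invert the inversion: P ~ sin(theta) exp(-F/RT), normalized over bins."""
    p = np.sin(np.radians(pmf.bin_centers)) * np.exp(
        -pmf.free_energy / rt(temperature)
    )
    return p / p.sum()


def tilt_modulus(
    pmf: PMFProfile,
    temperature: float = DEFAULT_TEMPERATURE,
    window_rt_multiple: float = 2.0,
) -> QuadraticFit:
    """Quadratic fit of the PMF near its minimum.

    The fit window is the contiguous run of occupied bins around the global
    minimum with F - F_min <= window_rt_multiple * R * T.  Returns the
    curvature chi (J/mol/deg^2) and the fitted equilibrium angle theta0.
    """
    if pmf.free_energy.size < 3:
        raise ValueError("PMF has fewer than 3 points")
    cutoff = window_rt_multiple * rt(temperature)
    inside = pmf.free_energy <= cutoff
    i_min = int(np.argmin(pmf.free_energy))
    lo = i_min
    while lo > 0 and inside[lo - 1]:
        lo -= 1
    hi = i_min
    while hi < len(inside) - 1 and inside[hi + 1]:
        hi += 1
    theta = pmf.bin_centers[lo : hi + 1]
    F = pmf.free_energy[lo : hi + 1]
    if theta.size < 3:
        raise ValueError(
            f"only {theta.size} PMF points within {window_rt_multiple} RT of "
            "the minimum; cannot fit a quadratic"
        )
    a, b, c = np.polyfit(theta, F, 2)
    chi = 2.0 * a
    if a > 0:
        theta0 = -b / (2.0 * a)
    else:
        chi = 0.0
        theta0 = float(pmf.bin_centers[i_min])
    resid = F - np.polyval([a, b, c], theta)
    ss_tot = float(np.sum((F - F.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return QuadraticFit(
        chi=float(chi),
        theta0=float(theta0),
        window=(float(theta[0]), float(theta[-1])),
        n_points=int(theta.size),
        r_squared=r2,
    )


def tilt_modulus_from_samples(
    samples: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    bin_width: float = 1.0,
    window_rt_multiple: float = 2.0,
) -> QuadraticFit:
    """Convenience: histogram -> Boltzmann inversion -> quadratic fit."""
    dist = tilt_distribution(samples, bin_width)
    pmf = boltzmann_invert(dist, temperature)
    return tilt_modulus(pmf, temperature, window_rt_multiple)


# ---------------------------------------------------------------------------
# splay
# ---------------------------------------------------------------------------


@dataclass
class SplaySamples:
    """Splay angles (deg, [0, 180]) per pair type, pooled over frames."""

    samples: dict[str, np.ndarray]

    @property
    def phi(self) -> dict[str, int]:
        return {k: int(v.size) for k, v in self.samples.items()}


def splay_angles(traj: Trajectory, cutoff: float = 1.0) -> SplaySamples:
    """Splay angles between director vectors of neighboring chains.

    Chains (cation or anion, keyed by their head heavy atom N or S) from two
    *different* complexes in the same leaflet whose head atoms lie within the
    lateral (xy) cutoff form a pair, classified ++ (cation-cation),
    -- (anion-anion) or +- (mixed).  The angle is between the two chain
    directors.  The intra-complex N-S pair is excluded.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    dirs = {
        "cation": chain_directors(traj, "cation"),
        "anion": chain_directors(traj, "anion"),
    }
    for t in dirs:
        dirs[t] = dirs[t] / np.linalg.norm(dirs[t], axis=-1, keepdims=True)
    heads = {
        t: traj.coordinates[:, traj.head_indices(t), :2] for t in ("cation", "anion")
    }
    n_mol = traj.n_molecules

    collected: dict[str, list[np.ndarray]] = {pt: [] for pt in PAIR_TYPES}
    for f in range(len(traj)):
        leaf = assign_leaflets(traj.frame(f), traj)
        chain_upper = {"cation": leaf.cation_upper, "anion": leaf.anion_upper}
        box_xy = traj.boxes[f, :2]
        for upper in (True, False):
            sel = {
                t: np.flatnonzero(chain_upper[t] == upper)
                for t in ("cation", "anion")
            }
            # stack both chain species of this leaflet into one neighbor search
            xy = np.concatenate([heads["cation"][f, sel["cation"]],
                                 heads["anion"][f, sel["anion"]]])
            dvec = np.concatenate([dirs["cation"][f, sel["cation"]],
                                   dirs["anion"][f, sel["anion"]]])
            is_cat = np.concatenate(
                [np.ones(sel["cation"].size, bool), np.zeros(sel["anion"].size, bool)]
            )
            mol_id = np.concatenate([sel["cation"], sel["anion"]])
            if xy.shape[0] < 2:
                continue
            delta = xy[:, None, :] - xy[None, :, :]
            delta -= box_xy * np.round(delta / box_xy)  # lateral minimum image
            dist = np.linalg.norm(delta, axis=-1)
            ii, jj = np.triu_indices(xy.shape[0], k=1)
            near = dist[ii, jj] < cutoff
            same_mol = mol_id[ii] == mol_id[jj]
            keep = near & ~same_mol
            ii, jj = ii[keep], jj[keep]
            if ii.size == 0:
                continue
            cosang = np.einsum("ij,ij->i", dvec[ii], dvec[jj])
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            both_cat = is_cat[ii] & is_cat[jj]
            both_ani = ~is_cat[ii] & ~is_cat[jj]
            collected["++"].append(ang[both_cat])
            collected["--"].append(ang[both_ani])
            collected["+-"].append(ang[~both_cat & ~both_ani])

    out = {
        pt: (np.concatenate(v) if v else np.empty(0)) for pt, v in collected.items()
    }
    if all(v.size == 0 for v in out.values()):
        warnings.warn(f"no chain pairs found within cutoff {cutoff} nm")
    return SplaySamples(out)


def splay_modulus(
    samples: SplaySamples,
    temperature: float = DEFAULT_TEMPERATURE,
    bin_width: float = 1.0,
    window_rt_multiple: float = 2.0,
) -> SplayResult:
    """Per-pair-type splay moduli chi_ij in k_B T (per rad^2).

    Shares the Boltzmann-inversion + quadratic-fit path with the tilt
    modulus; the fitted curvature (J/mol/deg^2) is converted to k_B T.
    Pair types with too few occupied bins are omitted with a warning;
    delta-like distributions are flagged as the stiff limit (chi = inf).
    """
    chi: dict[str, float] = {}
    phi: dict[str, int] = {}
    fits: dict[str, QuadraticFit] = {}
    for pt, ang in samples.samples.items():
        if ang.size == 0:
            warnings.warn(f"no splay samples for pair type {pt}; omitted")
            continue
        edges = np.arange(0.0, 180.0 + bin_width, bin_width)
        counts, _ = np.histogram(ang, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        occupied = int(np.count_nonzero(counts))
        if occupied == 1:
            warnings.warn(
                f"pair type {pt}: delta-like splay distribution (stiff limit); "
                "modulus reported as inf"
            )
            chi[pt] = math.inf
            phi[pt] = int(ang.size)
            continue
        if occupied < 3:
            warnings.warn(f"pair type {pt}: fewer than 3 occupied bins; omitted")
            continue
        dist = TiltDistribution(centers, counts / counts.sum(), bin_width)
        pmf = boltzmann_invert(dist, temperature)
        fit = tilt_modulus(pmf, temperature, window_rt_multiple)
        chi[pt] = molar_deg2_to_kbt_rad2(fit.chi, temperature)
        phi[pt] = int(ang.size)
        fits[pt] = fit
    return SplayResult(chi=chi, phi=phi, fits=fits)


def effective_bending_rigidity(
    chi_splay: dict[str, float], phi: dict[str, int]
) -> float:
    """phi-weighted harmonic mean of the splay moduli, in k_B T.

    1/KC_eff = sum_ij(phi_ij / chi_ij) / sum_ij(phi_ij).
    """
    common = [k for k in chi_splay if k in phi and phi[k] > 0]
    if not common:
        raise ValueError("no pair types with positive weight")
    total = sum(phi[k] for k in common)
    inv = 0.0
    for k in common:
        if chi_splay[k] <= 0:
            raise ValueError(f"pair type {k}: modulus must be positive")
        inv += phi[k] / chi_splay[k]
    return total / inv
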