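"""Synthetic bilayer trajectories with known ground truth.

The generator emulates the *statistical* structure that the estimators in
:mod:`ipabilayer.structural` and :mod:`ipabilayer.mechanical` consume, not an
energetically realistic membrane: alkyl chains are ideal-geometry united-atom
chains (bond length 0.153 nm, bond angle 114 deg) whose rotatable dihedrals
are independently trans (180 deg) or gauche (+-60 deg) with a configurable
probability; chain directors are drawn from the tilt distribution
P(theta) ~ sin(theta) * exp(-chi (theta - theta0)^2 / (2 R T)) by rejection
sampling; head groups sit on flat planes with a configurable N-S offset; and
the lateral box area fluctuates i.i.d. Gaussian with a configurable variance,
so a target area expansion modulus can be embedded exactly by inverting the
fluctuation formula.  There is no excluded volume and no water: molecular
overlap is allowed by design, and the box z extent is simply padded.

Every generated trajectory is paired with a :class:`GroundTruth` record so
estimators can be tested by parameter recovery.  Fixed seeds give
bit-identical output.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .constants import DEFAULT_TEMPERATURE, area_variance_for_ka, kbt, rt
from .model import (
    IPAComposition,
    MoleculeTopology,
    Trajectory,
    default_topology_spec,
    write_trajectory,
)

BOND_LENGTH = 0.153  # nm, C-C
BOND_ANGLE = 114.0  # deg, C-C-C
TRANS_ANGLE = 180.0
GAUCHE_ANGLE = 60.0


@dataclass
class SyntheticSpec:
    """Ground-truth parameters embedded in a generated trajectory.

    ``mean_area`` is the mean lateral box area in nm^2 (area per molecule
    times ``n_per_leaflet``); ``area_variance`` its variance in nm^4.
    ``tilt_chi`` is the curvature of the tilt free energy in J/mol/deg^2 and
    ``tilt_theta0`` the equilibrium tilt in degrees.  ``head_plane_offset``
    is the signed z offset of the nitrogen plane minus the sulfur plane, in
    nm (0 reproduces the head-alignment property of real IPA bilayers).
    ``area_ar1`` adds optional AR(1) autocorrelation to the area series
    (default 0: i.i.d.), for exercising block-average diagnostics.
    """

    composition: IPAComposition = field(
        default_factory=lambda: IPAComposition(16, 16)
    )
    n_per_leaflet: int = 64
    n_frames: int = 100
    p_gauche: float = 0.2
    tilt_theta0: float = 20.0
    tilt_chi: float = 20.0  # J/mol/deg^2
    mean_area: float = 28.8  # nm^2  (0.45 nm^2 per complex at N=64)
    area_variance: float = 2.6e-3  # nm^4
    head_plane_offset: float = 0.0  # nm
    head_plane_z: float = 2.0  # nm, |z| of the nitrogen planes
    area_ar1: float = 0.0
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_gauche <= 1.0:
            raise ValueError("p_gauche must lie in [0, 1]")
        if self.area_variance < 0:
            raise ValueError("area_variance must be nonnegative")
        if self.tilt_chi < 0:
            raise ValueError("tilt_chi must be nonnegative")
        if self.n_per_leaflet < 1 or self.n_frames < 1:
            raise ValueError("n_per_leaflet and n_frames must be positive")

    @property
    def implied_ka_mN_per_m(self) -> float:
        """Area expansion modulus implied by the fluctuation relation."""
        if self.area_variance == 0:
            return math.inf
        return (
            kbt(self.temperature)
            * self.mean_area
            * 1.0e21
            / (self.n_per_leaflet * self.area_variance)
        )


@dataclass
class GroundTruth:
    """Realized per-trajectory values written alongside every trajectory."""

    spec: SyntheticSpec
    implied_ka_mN_per_m: float
    midplane_z: float
    realized_mean_area: float
    realized_area_variance: float
    realized_gauche_fraction: float
    realized_mean_tilt: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        data["spec"]["composition"] = {
            "m": self.spec.composition.m,
            "n": self.spec.composition.n,
            "abbreviation": self.spec.composition.abbreviation,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)


# ---------------------------------------------------------------------------
# chain construction
# ---------------------------------------------------------------------------


def chains_from_dihedrals(
    dihedrals_deg: np.ndarray,
    bond_length: float = BOND_LENGTH,
    bond_angle_deg: float = BOND_ANGLE,
) -> np.ndarray:
    """Build (K, L, 3) chain coordinates from (K, L-3) dihedral angles.

    Standard internal-coordinate (NeRF) construction with fixed bond length
    and bond angle; dihedrals follow the IUPAC convention (trans = 180 deg,
    cis = 0).  C1 sits at the origin with the first bond along +z.
    """
    dihedrals_deg = np.atleast_2d(np.asarray(dihedrals_deg, dtype=float))
    n_chains, n_dih = dihedrals_deg.shape
    length = n_dih + 3
    b = bond_length
    theta = math.radians(bond_angle_deg)
    sup = math.pi - theta  # supplement: angle between consecutive bond vectors

    coords = np.zeros((n_chains, length, 3))
    coords[:, 1] = [0.0, 0.0, b]
    coords[:, 2] = coords[:, 1] + b * np.array([math.sin(sup), 0.0, math.cos(sup)])

    phi = np.radians(dihedrals_deg)
    cosp, sinp = np.cos(phi), np.sin(phi)
    for j in range(3, length):
        ab = coords[:, j - 2] - coords[:, j - 3]
        bc = coords[:, j - 1] - coords[:, j - 2]
        bc_hat = bc / np.linalg.norm(bc, axis=1, keepdims=True)
        nvec = np.cross(ab, bc_hat)
        nvec /= np.linalg.norm(nvec, axis=1, keepdims=True)
        mvec = np.cross(nvec, bc_hat)
        k = j - 3
        d = (
            b * math.cos(sup) * bc_hat
            + b * math.sin(sup) * (cosp[:, k, None] * mvec + sinp[:, k, None] * nvec)
        )
        coords[:, j] = coords[:, j - 1] + d
    return coords


def sample_dihedrals(
    n_chains: int, length: int, p_gauche: float, rng: np.random.Generator
) -> np.ndarray:
    """(n_chains, length-3) dihedral matrix: trans with prob 1-p, else +-60."""
    if length < 2:
        raise ValueError("chain length must be >= 2")
    n_dih = max(length - 3, 0)
    gauche = rng.random((n_chains, n_dih)) < p_gauche
    sign = np.where(rng.random((n_chains, n_dih)) < 0.5, 1.0, -1.0)
    return np.where(gauche, sign * GAUCHE_ANGLE, TRANS_ANGLE)


def build_chain(
    length: int, p_gauche: float, rng: np.random.Generator
) -> np.ndarray:
    """Build one united-atom alkyl chain; returns (length, 3) coordinates (nm)."""
    if length < 2:
        raise ValueError("chain length must be >= 2")
    if length == 2:
        return np.array([[0.0, 0.0, 0.0], [0.0, 0.0, BOND_LENGTH]])
    if length == 3:
        return chains_from_dihedrals(np.empty((1, 0)))[0]
    dih = sample_dihedrals(1, length, p_gauche, rng)
    return chains_from_dihedrals(dih)[0]


# ---------------------------------------------------------------------------
# tilt sampling
# ---------------------------------------------------------------------------


def tilt_density(
    theta_deg: np.ndarray,
    theta0: float,
    chi: float,
    temperature: float = DEFAULT_TEMPERATURE,
) -> np.ndarray:
    """Unnormalized tilt density sin(theta) exp(-chi (theta-theta0)^2 / 2RT)."""
    theta_deg = np.asarray(theta_deg, dtype=float)
    return np.sin(np.radians(theta_deg)) * np.exp(
        -chi * (theta_deg - theta0) ** 2 / (2.0 * rt(temperature))
    )


def sample_tilt_angles(
    n: int,
    theta0: float,
    chi: float,
    rng: np.random.Generator,
    temperature: float = DEFAULT_TEMPERATURE,
) -> np.ndarray:
    """Draw n tilt angles (degrees, in [0, 90]) by rejection sampling."""
    grid = np.linspace(0.0, 90.0, 9001)
    envelope = tilt_density(grid, theta0, chi, temperature).max() * 1.0001
    if envelope <= 0:
        raise ValueError("tilt density vanishes on [0, 90]")
    out = np.empty(n)
    filled = 0
    while filled < n:
        batch = max(2 * (n - filled), 1024)
        prop = rng.random(batch) * 90.0
        accept = rng.random(batch) * envelope < tilt_density(
            prop, theta0, chi, temperature
        )
        take = prop[accept][: n - filled]
        out[filled : filled + take.size] = take
        filled += take.size
    return out


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------


def _rotation_about_axis(axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrices, vectorized: (K,3) axes, (K,) angles -> (K,3,3)."""
    axis = axis / np.linalg.norm(axis, axis=-1, keepdims=True)
    x, y, z = axis[:, 0], axis[:, 1], axis[:, 2]
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.stack(
        [
            np.stack([c + x * x * C, x * y * C - z * s, x * z * C + y * s], axis=-1),
            np.stack([y * x * C + z * s, c + y * y * C, y * z * C - x * s], axis=-1),
            np.stack([z * x * C - y * s, z * y * C + x * s, c + z * z * C], axis=-1),
        ],
        axis=-2,
    )


def _align_rotation(u: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Rotation matrices mapping unit vectors u onto unit vectors d."""
    v = np.cross(u, d)
    s = np.linalg.norm(v, axis=-1)
    c = np.einsum("ij,ij->i", u, d)
    R = np.tile(np.eye(3), (len(u), 1, 1))
    ok = s > 1e-12
    if np.any(ok):
        angle = np.arctan2(s[ok], c[ok])
        R[ok] = _rotation_about_axis(v[ok], angle)
    flip = (~ok) & (c < 0)
    if np.any(flip):
        # antiparallel: rotate 180 deg about any axis perpendicular to u
        perp = np.cross(u[flip], np.array([1.0, 0.0, 0.0]))
        degenerate = np.linalg.norm(perp, axis=-1) < 1e-8
        perp[degenerate] = np.cross(u[flip][degenerate], np.array([0.0, 1.0, 0.0]))
        R[flip] = _rotation_about_axis(perp, np.full(int(flip.sum()), math.pi))
    return R


def _orient_chains(
    chains: np.ndarray,
    tilt_deg: np.ndarray,
    azimuth: np.ndarray,
    spin: np.ndarray,
    inward_sign: float,
) -> np.ndarray:
    """Rotate chains so each director points inward at its sampled tilt.

    The director (C1 -> second-last carbon) is mapped exactly onto the target
    direction, so the measured tilt of the oriented chain equals the drawn
    angle; a uniform spin about the director randomizes the chain's azimuthal
    conformation, which the order-parameter math assumes.
    """
    director = chains[:, -2] - chains[:, 0]
    u = director / np.linalg.norm(director, axis=-1, keepdims=True)
    th = np.radians(tilt_deg)
    target = np.stack(
        [
            np.sin(th) * np.cos(azimuth),
            np.sin(th) * np.sin(azimuth),
            inward_sign * np.cos(th),
        ],
        axis=-1,
    )
    R = _align_rotation(u, target) @ _rotation_about_axis(u, spin)
    return np.einsum("kij,klj->kli", R, chains - chains[:, :1]), target


# ---------------------------------------------------------------------------
# frame / trajectory generation
# ---------------------------------------------------------------------------


def _lattice(n: int) -> np.ndarray:
    """Unit-square lattice positions for n sites (padded square grid)."""
    side = math.ceil(math.sqrt(n))
    i, j = np.divmod(np.arange(n), side)
    return (np.stack([i, j], axis=-1) + 0.5) / side


def sample_area_series(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-frame lateral areas (nm^2): Gaussian, optionally AR(1)-correlated.

    Non-positive draws are redrawn (with a warning); persistent failure is an
    error, which can only happen for pathological mean/variance combinations.
    """
    sd = math.sqrt(spec.area_variance)
    if spec.area_ar1 == 0.0:
        areas = rng.normal(spec.mean_area, sd, spec.n_frames)
    else:
        rho = spec.area_ar1
        innov = rng.normal(0.0, sd * math.sqrt(1.0 - rho**2), spec.n_frames)
        areas = np.empty(spec.n_frames)
        prev = rng.normal(0.0, sd)
        for i in range(spec.n_frames):
            prev = rho * prev + innov[i]
            areas[i] = spec.mean_area + prev
    bad = areas <= 0
    attempts = 0
    while np.any(bad):
        warnings.warn("redrawing non-positive lateral area samples")
        areas[bad] = rng.normal(spec.mean_area, sd, int(bad.sum()))
        bad = areas <= 0
        attempts += 1
        if attempts > 100:
            raise RuntimeError("could not draw positive lateral areas")
    return areas


def _molecule_topologies(spec: SyntheticSpec) -> list[MoleculeTopology]:
    m, n = spec.composition.m, spec.composition.n
    per_mol = 2 + m + n
    mols = []
    for k in range(2 * spec.n_per_leaflet):
        base = k * per_mol
        mols.append(
            MoleculeTopology(
                head_cation=base,
                head_anion=base + 1 + m,
                cation_chain=tuple(range(base + 1, base + 1 + m)),
                anion_chain=tuple(range(base + 2 + m, base + 2 + m + n)),
            )
        )
    return mols


def _generate_coordinates(
    spec: SyntheticSpec, areas: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    """All-frame coordinate tensor (F, A, 3) plus realized statistics."""
    m, n = spec.composition.m, spec.composition.n
    F = len(areas)
    N = spec.n_per_leaflet
    per_mol = 2 + m + n
    n_atoms = 2 * N * per_mol
    coords = np.empty((F, n_atoms, 3))

    unit_xy = _lattice(N)  # (N, 2)
    side = np.sqrt(areas)  # (F,)
    gauche_states = []
    mean_tilt: dict[str, float] = {}

    for leaflet, sign in (("upper", 1.0), ("lower", -1.0)):
        xy = unit_xy[None, :, :] * side[:, None, None]  # (F, N, 2)
        z_n = sign * spec.head_plane_z
        z_s = sign * spec.head_plane_z - sign * spec.head_plane_offset
        for chain_type, length, head_z, head_shift in (
            ("cation", m, z_n, 0.0),
            ("anion", n, z_s, 0.15),
        ):
            K = F * N
            dih = sample_dihedrals(K, length, spec.p_gauche, rng)
            gauche_states.append(np.abs(dih) < 120.0)
            chains = chains_from_dihedrals(dih)  # (K, L, 3)
            tilt = sample_tilt_angles(
                K, spec.tilt_theta0, spec.tilt_chi, rng, spec.temperature
            )
            azim = rng.random(K) * 2.0 * math.pi
            spin = rng.random(K) * 2.0 * math.pi
            oriented, target = _orient_chains(chains, tilt, azim, spin, -sign)
            key = f"{leaflet}:{chain_type}"
            mean_tilt[key] = float(tilt.mean())

            heads = np.empty((F, N, 3))
            heads[:, :, :2] = xy + head_shift
            heads[:, :, 2] = head_z
            heads_flat = heads.reshape(K, 3)
            c1 = heads_flat + BOND_LENGTH * target
            placed = (oriented + c1[:, None, :]).reshape(F, N, length, 3)

            # scatter into the canonical atom layout
            mol_offset = 0 if leaflet == "upper" else N
            base = (mol_offset + np.arange(N)) * per_mol
            if chain_type == "cation":
                head_idx, chain0 = base, base + 1
            else:
                head_idx, chain0 = base + 1 + m, base + 2 + m
            coords[:, head_idx, :] = heads
            chain_cols = chain0[:, None] + np.arange(length)[None, :]
            coords[:, chain_cols, :] = placed

    realized = {
        "gauche_fraction": float(np.concatenate([g.ravel() for g in gauche_states]).mean())
        if any(g.size for g in gauche_states)
        else 0.0,
        "mean_tilt": {
            "cation": float(
                np.mean([v for k, v in mean_tilt.items() if k.endswith("cation")])
            ),
            "anion": float(
                np.mean([v for k, v in mean_tilt.items() if k.endswith("anion")])
            ),
        },
    }
    return coords, realized


def generate_frame(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    area: float | None = None,
) -> "np.ndarray":
    """Generate a single frame's coordinates at the given lateral area."""
    a = spec.mean_area if area is None else area
    coords, _ = _generate_coordinates(spec, np.array([a]), rng)
    return coords[0]


def generate_trajectory(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Generate a full trajectory plus its ground-truth record.

    Deterministic for a fixed ``spec.seed``: identical specs give
    bit-identical trajectories and ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    areas = sample_area_series(spec, rng)
    coords, realized = _generate_coordinates(spec, areas, rng)

    boxes = np.empty((len(areas), 3))
    boxes[:, 0] = boxes[:, 1] = np.sqrt(areas)
    max_extent = spec.head_plane_z + BOND_LENGTH * max(
        spec.composition.m, spec.composition.n
    )
    boxes[:, 2] = 2.0 * max_extent + 2.0  # padded; no water is generated

    traj = Trajectory(
        coords,
        boxes,
        np.arange(len(areas), dtype=float) * 10.0,  # 10 ps spacing
        _molecule_topologies(spec),
        spec.composition,
        spec.n_per_leaflet,
    )
    gt = GroundTruth(
        spec=spec,
        implied_ka_mN_per_m=spec.implied_ka_mN_per_m,
        midplane_z=0.0,
        realized_mean_area=float(areas.mean()),
        realized_area_variance=float(areas.var()),
        realized_gauche_fraction=realized["gauche_fraction"],
        realized_mean_tilt=realized["mean_tilt"],
    )
    return traj, gt


def gel_like_spec(
    n_per_leaflet: int = 64, n_frames: int = 240, seed: int = 0
) -> SyntheticSpec:
    """Ground truth emulating an ordered gel-phase bilayer (16-16-like).

    Tight area (0.425 nm^2 per complex), stiff near-vertical tilt
    (chi = 80 J/mol/deg^2 about theta0 = 0 so neighboring directors stay
    nearly parallel, as in an untilted gel), few gauche defects, and an area
    variance embedding K_A = 1500 mN/m.  All six phase votes land on the gel
    side of their thresholds.
    """
    a = 0.425
    ka = 1500.0
    return SyntheticSpec(
        composition=IPAComposition(16, 16),
        n_per_leaflet=n_per_leaflet,
        n_frames=n_frames,
        p_gauche=0.05,
        tilt_theta0=0.0,
        tilt_chi=80.0,
        mean_area=a * n_per_leaflet,
        area_variance=area_variance_for_ka(ka, a * n_per_leaflet, n_per_leaflet),
        seed=seed,
    )


def fluid_like_spec(
    n_per_leaflet: int = 64, n_frames: int = 240, seed: int = 0
) -> SyntheticSpec:
    """Ground truth emulating a liquid-disordered bilayer (10-10-like).

    Loose area (0.50 nm^2 per complex), soft broad tilt (chi = 3 J/mol/deg^2
    about theta0 = 30), abundant gauche defects, K_A = 450 mN/m.  All six
    phase votes land on the Ld side.
    """
    a = 0.50
    ka = 450.0
    return SyntheticSpec(
        composition=IPAComposition(10, 10),
        n_per_leaflet=n_per_leaflet,
        n_frames=n_frames,
        p_gauche=0.25,
        tilt_theta0=30.0,
        tilt_chi=3.0,
        mean_area=a * n_per_leaflet,
        area_variance=area_variance_for_ka(ka, a * n_per_leaflet, n_per_leaflet),
        seed=seed,
    )


def write_dataset(
    traj: Trajectory,
    ground_truth: GroundTruth,
    outdir: str | Path,
    prefix: str = "bilayer",
) -> dict[str, Path]:
    """Write GRO + XTC + ground-truth sidecar + topology declaration."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gro": outdir / f"{prefix}.gro",
        "xtc": outdir / f"{prefix}.xtc",
        "ground_truth": outdir / f"{prefix}.ground_truth.json",
        "topology": outdir / f"{prefix}.topology.yaml",
    }
    write_trajectory(traj, paths["gro"], paths["xtc"])
    ground_truth.to_json(paths["ground_truth"])
    default_topology_spec(traj.composition).to_yaml(paths["topology"])
    return paths
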