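"""Domain model for ion-pair-amphiphile (IPA) bilayers.

An IPA complex pairs a cationic alkyltrimethylammonium surfactant with an
m-carbon chain and an anionic alkylsulfate surfactant with an n-carbon chain,
held together by head-group electrostatics so the complex behaves like a
pseudo double-chained lipid.  This module holds the composition arithmetic
(total carbon count and the asymmetry index ``delta_c = m - (n + 1)``, which
accounts for the one-atom offset between the cation's first chain carbon and
the sulfate bridging oxygen), per-molecule atom indexing, in-memory trajectory
containers, leaflet/midplane geometry, and GRO/XTC file I/O via MDAnalysis.

Conventions: lengths in nm, times in ps, the bilayer normal is the z axis.
Carbon numbering starts at C1 on the carbon bonded to the charged head
(N for the cation, the sulfate bridging oxygen for the anion) and increases
toward the terminal methyl.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

_ABBREV_CATION = {16: "HTMA", 14: "TTMA", 12: "DTMA", 10: "DeTA"}
_ABBREV_ANION = {16: "HS", 14: "TS", 12: "DS", 10: "DeS"}


class InvalidCompositionError(ValueError):
    """Raised for non-positive chain lengths."""


def delta_c(m: int, n: int) -> int:
    """Alkyl-chain asymmetry index ``m - (n + 1)``.

    The +1 reflects the intrinsic one-atom offset of the pair: the sulfate
    bridging oxygen of the anion sits at the height of the cation's first
    chain carbon, so even an m = n complex is structurally asymmetric.
    """
    _check_lengths(m, n)
    return m - (n + 1)


def total_carbons(m: int, n: int) -> int:
    """Total alkyl carbon number of the complex, m + n."""
    _check_lengths(m, n)
    return m + n


def _check_lengths(m: int, n: int) -> None:
    if m < 1 or n < 1:
        raise InvalidCompositionError(
            f"chain lengths must be positive integers, got m={m}, n={n}"
        )


def composition_abbreviation(m: int, n: int) -> str:
    cat = _ABBREV_CATION.get(m, f"C{m}TMA")
    ani = _ABBREV_ANION.get(n, f"C{n}S")
    return f"{cat}-{ani}"


@dataclass(frozen=True)
class IPAComposition:
    """One C_mTMA+ / C_nS- pairing."""

    m: int
    n: int
    abbreviation: str = ""

    def __post_init__(self):
        _check_lengths(self.m, self.n)
        if not self.abbreviation:
            object.__setattr__(
                self, "abbreviation", composition_abbreviation(self.m, self.n)
            )

    @property
    def total_carbons(self) -> int:
        return total_carbons(self.m, self.n)

    @property
    def delta_c(self) -> int:
        return delta_c(self.m, self.n)


@dataclass(frozen=True)
class MoleculeTopology:
    """Atom indices (into the frame coordinate array) for one IPA complex.

    ``cation_chain[0]`` is C1 bonded to the head nitrogen; ``anion_chain[0]``
    is C1 bonded to the sulfate bridging oxygen.
    """

    head_cation: int
    head_anion: int
    cation_chain: tuple[int, ...]
    anion_chain: tuple[int, ...]

    def __post_init__(self):
        for name, chain in (
            ("cation_chain", self.cation_chain),
            ("anion_chain", self.anion_chain),
        ):
            if len(set(chain)) != len(chain):
                raise ValueError(f"{name} contains duplicate atom indices")

    def validate_against(self, composition: IPAComposition) -> None:
        if len(self.cation_chain) != composition.m:
            raise ValueError(
                f"cation chain has {len(self.cation_chain)} carbons, "
                f"composition declares m={composition.m}"
            )
        if len(self.anion_chain) != composition.n:
            raise ValueError(
                f"anion chain has {len(self.anion_chain)} carbons, "
                f"composition declares n={composition.n}"
            )


@dataclass
class Frame:
    """Coordinates (atoms x 3, nm), orthorhombic box (Lx, Ly, Lz, nm), time (ps)."""

    coordinates: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")

    @property
    def lateral_area(self) -> float:
        return float(self.box[0] * self.box[1])


@dataclass
class Trajectory:
    """An in-memory bilayer trajectory.

    Coordinates are stored as one (n_frames, n_atoms, 3) array; :class:`Frame`
    objects returned by indexing are views into it.
    """

    coordinates: np.ndarray  # (F, A, 3) nm
    boxes: np.ndarray  # (F, 3) nm
    times: np.ndarray  # (F,) ps
    molecules: list[MoleculeTopology]
    composition: IPAComposition
    n_per_leaflet: int

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if len(self.boxes) != len(self.coordinates):
            raise ValueError("one box per frame required")
        if not self.molecules:
            raise ValueError("trajectory has no molecules")
        for mol in self.molecules:
            mol.validate_against(self.composition)
        # cached per-chain index matrices for vectorized analyses
        self._cation_idx = np.array([m.cation_chain for m in self.molecules])
        self._anion_idx = np.array([m.anion_chain for m in self.molecules])
        self._head_n_idx = np.array([m.head_cation for m in self.molecules])
        self._head_s_idx = np.array([m.head_anion for m in self.molecules])

    def __len__(self) -> int:
        return len(self.coordinates)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def frame(self, i: int) -> Frame:
        return Frame(self.coordinates[i], self.boxes[i], float(self.times[i]))

    def __iter__(self):
        for i in range(len(self)):
            yield self.frame(i)

    def chain_indices(self, chain_type: str) -> np.ndarray:
        """(n_molecules, chain_length) carbon index matrix for one chain type."""
        if chain_type == "cation":
            return self._cation_idx
        if chain_type == "anion":
            return self._anion_idx
        raise ValueError(f"unknown chain type {chain_type!r}")

    def head_indices(self, chain_type: str) -> np.ndarray:
        if chain_type == "cation":
            return self._head_n_idx
        if chain_type == "anion":
            return self._head_s_idx
        raise ValueError(f"unknown chain type {chain_type!r}")

    def lateral_areas(self) -> np.ndarray:
        return self.boxes[:, 0] * self.boxes[:, 1]

    def sliced(self, start: int = 0, stop: int | None = None) -> "Trajectory":
        return Trajectory(
            self.coordinates[start:stop],
            self.boxes[start:stop],
            self.times[start:stop],
            self.molecules,
            self.composition,
            self.n_per_leaflet,
        )


@dataclass
class LeafletMap:
    """Per-molecule and per-chain leaflet assignment for one frame.

    Arrays are boolean, True = upper leaflet.  The complex as a whole follows
    its cation head nitrogen; the anion chain follows its own sulfur, so the
    two can in principle disagree for interdigitated configurations.
    """

    molecule_upper: np.ndarray
    cation_upper: np.ndarray
    anion_upper: np.ndarray

    def __getitem__(self, i: int) -> str:
        return "upper" if self.molecule_upper[i] else "lower"

    @property
    def n_upper(self) -> int:
        return int(np.count_nonzero(self.molecule_upper))

    @property
    def n_lower(self) -> int:
        return int(len(self.molecule_upper) - self.n_upper)


def bilayer_midplane(frame: Frame, traj: Trajectory) -> float:
    """Mean z of all chain carbon atoms: the reference plane of the bilayer."""
    if not traj.molecules:
        raise ValueError("trajectory has no molecules")
    chain_atoms = np.concatenate(
        [traj.chain_indices("cation").ravel(), traj.chain_indices("anion").ravel()]
    )
    return float(frame.coordinates[chain_atoms, 2].mean())


def assign_leaflets(frame: Frame, traj: Trajectory) -> LeafletMap:
    """Assign molecules to leaflets by head z relative to the midplane.

    The complex is upper iff its head nitrogen sits above the midplane; the
    anion chain is assigned by its own sulfur z.  Heads exactly on the
    midplane fall back to the sign of their chain centroid (with a warning).
    """
    mid = bilayer_midplane(frame, traj)
    z = frame.coordinates[:, 2]

    def _assign(head_idx: np.ndarray, chain_idx: np.ndarray) -> np.ndarray:
        dz = z[head_idx] - mid
        upper = dz > 0
        on_plane = dz == 0
        if np.any(on_plane):
            warnings.warn(
                "head group exactly on the midplane; assigning by chain centroid",
                stacklevel=3,
            )
            centroid_dz = z[chain_idx].mean(axis=1) - mid
            upper = np.where(on_plane, centroid_dz > 0, upper)
        return upper

    mol_upper = _assign(traj.head_indices("cation"), traj.chain_indices("cation"))
    anion_upper = _assign(traj.head_indices("anion"), traj.chain_indices("anion"))
    n_up = int(np.count_nonzero(mol_upper))
    if n_up == 0 or n_up == len(mol_upper):
        warnings.warn("all molecules assigned to one leaflet", stacklevel=2)
    return LeafletMap(mol_upper, mol_upper.copy(), anion_upper)


# ---------------------------------------------------------------------------
# file I/O (GRO / PDB coordinates, XTC / DCD trajectories) via MDAnalysis
# ---------------------------------------------------------------------------


@dataclass
class TopologySpec:
    """Maps residue names to their role (cation/anion) and chain length."""

    residues: Mapping[str, tuple[str, int]]  # name -> (role, chain_length)

    @classmethod
    def from_mapping(cls, data: Mapping) -> "TopologySpec":
        residues = {}
        for name, info in data["residues"].items():
            role = info["role"]
            if role not in ("cation", "anion"):
                raise ValueError(f"residue {name}: unknown role {role!r}")
            residues[name] = (role, int(info["chain_length"]))
        return cls(residues)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TopologySpec":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "residues": {
                name: {"role": role, "chain_length": length}
                for name, (role, length) in self.residues.items()
            }
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


def _rejoin_molecules(coords: np.ndarray, box: np.ndarray, groups: Sequence[np.ndarray]):
    """Minimum-image re-join each molecule by walking its atom chain.

    Chains must be geometrically contiguous for tilt/dihedral math; trajectory
    formats may wrap atoms across periodic boundaries.  Each atom is shifted
    to the minimum image of its predecessor in the listed order (head, C1,
    C2, ...), so bonded steps — always far below half a box edge — decide the
    image, not the distance to the head.
    """
    for idx in groups:
        pts = coords[idx]
        steps = np.diff(pts, axis=0)
        steps -= box * np.round(steps / box)
        coords[idx[1:]] = pts[0] + np.cumsum(steps, axis=0)


def load_trajectory(
    coord_path: str | Path,
    traj_path: str | Path | None,
    topology_spec: TopologySpec | Mapping | str | Path,
    rejoin: bool = True,
) -> Trajectory:
    """Read a GRO/PDB coordinate file plus optional XTC/DCD trajectory.

    Units are normalized to nm and ps regardless of the on-disk dialect
    (MDAnalysis reports Angstrom internally; PDB files in Angstrom are divided
    by 10).  Molecules are re-joined across periodic boundaries per chain.
    """
    import MDAnalysis as mda

    if isinstance(topology_spec, (str, Path)):
        spec = TopologySpec.from_yaml(topology_spec)
    elif isinstance(topology_spec, TopologySpec):
        spec = topology_spec
    else:
        spec = TopologySpec.from_mapping(topology_spec)

    try:
        if traj_path is None:
            u = mda.Universe(str(coord_path))
        else:
            u = mda.Universe(str(coord_path), str(traj_path))
    except (OSError, EOFError, ValueError) as exc:
        raise IOError(f"failed to read trajectory: {exc}") from exc

    cat_residues, ani_residues = [], []
    for res in u.residues:
        if res.resname not in spec.residues:
            raise ValueError(
                f"unknown residue name {res.resname!r}; declare it in the topology spec"
            )
        role, length = spec.residues[res.resname]
        names = list(res.atoms.names)
        head_name = "N" if role == "cation" else "S"
        if head_name not in names:
            raise ValueError(
                f"residue {res.resname} lacks the head atom {head_name!r}"
            )
        head = int(res.atoms.indices[names.index(head_name)])
        chain = []
        for k in range(1, length + 1):
            cname = f"C{k}"
            if cname not in names:
                raise ValueError(
                    f"residue {res.resname}: missing chain carbon {cname} "
                    f"(declared length {length})"
                )
            chain.append(int(res.atoms.indices[names.index(cname)]))
        target = cat_residues if role == "cation" else ani_residues
        target.append((head, tuple(chain), length))

    if len(cat_residues) != len(ani_residues):
        raise ValueError(
            f"unbalanced residues: {len(cat_residues)} cations vs "
            f"{len(ani_residues)} anions"
        )
    if not cat_residues:
        raise ValueError("no IPA residues found")

    m = cat_residues[0][2]
    n = ani_residues[0][2]
    composition = IPAComposition(m, n)
    molecules = [
        MoleculeTopology(ch, ah, cchain, achain)
        for (ch, cchain, _), (ah, achain, _) in zip(cat_residues, ani_residues)
    ]

    frames, boxes, times = [], [], []
    try:
        for ts in u.trajectory:
            frames.append(ts.positions.astype(float) / 10.0)  # A -> nm
            boxes.append(np.asarray(ts.dimensions[:3], dtype=float) / 10.0)
            times.append(float(ts.time))
    except (OSError, EOFError, ValueError, RuntimeError) as exc:
        raise IOError(f"trajectory file is truncated or corrupt: {exc}") from exc

    coords = np.stack(frames)
    boxes_arr = np.stack(boxes)
    if rejoin:
        groups = [
            np.array((mol.head_cation,) + mol.cation_chain) for mol in molecules
        ] + [np.array((mol.head_anion,) + mol.anion_chain) for mol in molecules]
        for f in range(len(coords)):
            _rejoin_molecules(coords[f], boxes_arr[f], groups)

    n_mol = len(molecules)
    if n_mol % 2:
        logger.warning("odd molecule count %d; leaflets cannot be balanced", n_mol)
    traj = Trajectory(
        coords, boxes_arr, np.asarray(times), molecules, composition, n_mol // 2
    )
    logger.info(
        "loaded %d frames, %d molecules (%s)", len(traj), n_mol, composition.abbreviation
    )
    return traj


def _build_universe(traj: Trajectory):
    """MDAnalysis Universe mirroring the trajectory's residue layout."""
    import MDAnalysis as mda

    comp = traj.composition
    n_mol = traj.n_molecules
    atoms_per_mol = 2 + comp.m + comp.n
    n_atoms = n_mol * atoms_per_mol

    resindex = np.repeat(np.arange(2 * n_mol), [1 + comp.m, 1 + comp.n] * n_mol)
    u = mda.Universe.empty(
        n_atoms,
        n_residues=2 * n_mol,
        atom_resindex=resindex,
        residue_segindex=np.zeros(2 * n_mol, dtype=int),
        trajectory=True,
    )
    names = (["N"] + [f"C{k}" for k in range(1, comp.m + 1)]
             + ["S"] + [f"C{k}" for k in range(1, comp.n + 1)]) * n_mol
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", ["CTM", "SUL"] * n_mol)
    u.add_TopologyAttr("resids", list(range(1, 2 * n_mol + 1)))
    return u


def default_topology_spec(composition: IPAComposition) -> TopologySpec:
    """Topology declaration matching trajectories written by this package."""
    return TopologySpec(
        {
            "CTM": ("cation", composition.m),
            "SUL": ("anion", composition.n),
        }
    )


def write_trajectory(
    traj: Trajectory, gro_path: str | Path, xtc_path: str | Path | None = None
) -> None:
    """Write the first frame as GRO and (optionally) all frames as XTC.

    Assumes the canonical atom layout produced by the synthetic generator
    (per molecule: N, C1..Cm, S, C1..Cn).
    """
    import MDAnalysis as mda

    u = _build_universe(traj)
    dims = np.zeros(6)
    dims[3:] = 90.0

    u.atoms.positions = traj.coordinates[0] * 10.0  # nm -> A
    dims[:3] = traj.boxes[0] * 10.0
    u.dimensions = dims
    u.atoms.write(str(gro_path))

    if xtc_path is not None:
        with mda.Writer(str(xtc_path), n_atoms=len(u.atoms)) as w:
            for i in range(len(traj)):
                u.atoms.positions = traj.coordinates[i] * 10.0
                dims[:3] = traj.boxes[i] * 10.0
                u.dimensions = dims
                u.trajectory.ts.time = float(traj.times[i])
                u.trajectory.ts.frame = i
                w.write(u.atoms)
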