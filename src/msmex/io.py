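"""Topologies, trajectory ensembles, residue selections and run configuration.

The data model is deliberately light: a :class:`Topology` is a flat list of
labelled atoms plus a mapping from chain id to a biological role
(``receptor-alpha`` / ``receptor-beta`` / ``peptide`` / ``solvent`` /
``other``).  Chain roles are always supplied by the caller or a config file,
never guessed from chain letters.  Coordinates are Angstrom throughout;
residue numbering is 1-based so that labels like "beta-chain residue 82"
match the crystallographic convention.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K, ELEMENT_MASSES

CHAIN_ROLES = ("receptor-alpha", "receptor-beta", "peptide", "solvent", "other")


class ParseError(ValueError):
    """Raised when a structure file cannot be interpreted."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    res_id: int          # 1-based residue number within its chain
    res_name: str
    chain_id: str
    heavy: bool
    mass: float          # amu


@dataclass
class Topology:
    """Ordered atom list with chain role tags.

    Invariants (checked on construction): residue ids are non-decreasing
    within each chain, every atom's mass is positive, and no two atoms in
    the same residue share a name.
    """

    atoms: list[Atom]
    chain_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen_in_residue: set[tuple[str, int, str]] = set()
        last_res: dict[str, int] = {}
        for i, a in enumerate(self.atoms):
            if a.mass <= 0:
                raise ValueError(f"atom {i} ({a.name}) has non-positive mass")
            key = (a.chain_id, a.res_id, a.name)
            if key in seen_in_residue:
                raise ParseError(
                    f"duplicate atom {a.name!r} in residue "
                    f"{a.chain_id}{a.res_id}"
                )
            seen_in_residue.add(key)
            prev = last_res.get(a.chain_id)
            if prev is not None and a.res_id < prev:
                raise ValueError(
                    f"residue numbers not ordered in chain {a.chain_id}: "
                    f"{a.res_id} after {prev}"
                )
            last_res[a.chain_id] = a.res_id
        for role in self.chain_roles.values():
            if role not in CHAIN_ROLES:
                raise ValueError(f"unknown chain role {role!r}")

    # -- basic queries ----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residues(self) -> list[tuple[str, int]]:
        """Unique (chain_id, res_id) pairs in atom order."""
        out: list[tuple[str, int]] = []
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.res_id)
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def atom_indices(
        self,
        chain_id: str | None = None,
        res_id: int | None = None,
        name: str | None = None,
        heavy_only: bool = False,
        role: str | None = None,
    ) -> np.ndarray:
        idx = []
        for i, a in enumerate(self.atoms):
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if res_id is not None and a.res_id != res_id:
                continue
            if name is not None and a.name != name:
                continue
            if heavy_only and not a.heavy:
                continue
            if role is not None and self.chain_roles.get(a.chain_id) != role:
                continue
            idx.append(i)
        return np.asarray(idx, dtype=int)

    def ca_index(self, chain_id: str, res_id: int) -> int:
        """Index of the single CA atom of a residue; -1 if absent."""
        idx = self.atom_indices(chain_id=chain_id, res_id=res_id, name="CA")
        return int(idx[0]) if len(idx) else -1

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def heavy_mask(self) -> np.ndarray:
        return np.array([a.heavy for a in self.atoms], dtype=bool)


@dataclass
class TrajectoryEnsemble:
    """One or more coordinate series (frames x atoms x 3, Angstrom)
    recorded under a single named condition at a fixed frame interval."""

    condition_id: str
    trajectories: list[np.ndarray]
    frame_interval_ns: float
    topology: Topology

    def __post_init__(self) -> None:
        if self.frame_interval_ns <= 0:
            raise ValueError("frame interval must be > 0 ns")
        for t, xyz in enumerate(self.trajectories):
            xyz = np.asarray(xyz, dtype=float)
            if xyz.ndim != 3 or xyz.shape[2] != 3:
                raise ValueError(f"trajectory {t}: expected (frames, atoms, 3)")
            if xyz.shape[1] != self.topology.n_atoms:
                raise ValueError(
                    f"trajectory {t}: atom count mismatch — expected "
                    f"{self.topology.n_atoms}, found {xyz.shape[1]}"
                )
            if xyz.shape[0] < 2:
                raise ValueError(f"trajectory {t}: needs >= 2 frames")
            self.trajectories[t] = xyz

    @property
    def n_frames_total(self) -> int:
        return sum(x.shape[0] for x in self.trajectories)


@dataclass
class ResidueSelection:
    """Ordered, duplicate-free list of (chain_id, res_id) with provenance."""

    residues: list[tuple[str, int]]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("selection contains duplicate residues")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_pairs(self) -> int:
        n = len(self.residues)
        return n * (n - 1) // 2


@dataclass
class RunConfig:
    """All stage parameters of one analysis run.

    The seed is recorded in every manifest so a run can be reproduced
    bit-for-bit from its output directory.
    """

    seed: int = 0
    temperature_K: float = DEFAULT_TEMPERATURE_K
    tica_lag_frames: int = 10
    tica_n_components: int = 3
    kmeans_k: int = 100
    msm_lag_frames: int = 25
    msm_lag_candidates: tuple[int, ...] = (1, 2, 5, 10, 25, 50, 100)
    n_metastable: int = 3
    n_bootstrap: int = 50
    contact_cutoff_A: float = 4.0
    solvent_cutoff_A: float = 3.5
    chain_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["msm_lag_candidates"] = list(self.msm_lag_candidates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "msm_lag_candidates" in d:
            d["msm_lag_candidates"] = tuple(d["msm_lag_candidates"])
        return cls(**d)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _mass_for(element: str) -> float:
    try:
        return ELEMENT_MASSES[element.upper()]
    except KeyError:
        raise ParseError(f"element {element!r} not in the standard mass table")


def read_topology(path: str | Path, chain_roles: dict[str, str] | None = None) -> Topology:
    """Read a PDB file into a :class:`Topology`.

    Atom order is preserved; chain roles come from ``chain_roles`` (chains
    absent from the mapping get ``other``).  A malformed ATOM/HETATM record
    raises :class:`ParseError` naming the offending line.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    _scan_pdb_records(path)
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    atoms: list[Atom] = []
    for i in range(arr.array_length()):
        element = str(arr.element[i]) or "C"
        atoms.append(
            Atom(
                name=str(arr.atom_name[i]),
                element=element,
                res_id=int(arr.res_id[i]),
                res_name=str(arr.res_name[i]),
                chain_id=str(arr.chain_id[i]),
                heavy=element.upper() not in ("H", "D"),
                mass=_mass_for(element),
            )
        )
    roles = dict(chain_roles or {})
    for cid in {a.chain_id for a in atoms}:
        roles.setdefault(cid, "other")
    return Topology(atoms=atoms, chain_roles=roles)


def _scan_pdb_records(path: Path) -> None:
    # PDB fixed columns: serial 7-11, name 13-16, resSeq 23-26, xyz 31-54
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"{path.name}:{lineno}: truncated coordinate record")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[22:26])
            except ValueError:
                raise ParseError(f"{path.name}:{lineno}: malformed coordinate record")


def read_trajectory(
    topology: Topology,
    path: str | Path,
    frame_interval_ns: float,
    condition_id: str = "default",
) -> TrajectoryEnsemble:
    """Read a multi-model PDB or a DCD/XTC file as one trajectory.

    Binary formats go through mdtraj (which stores nm) and are converted to
    Angstrom.  The frame atom count must equal the topology's.
    """
    if frame_interval_ns <= 0:
        raise ValueError("frame interval must be > 0 ns")
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".pdb":
        from biotite.structure.io.pdb import PDBFile

        stack = PDBFile.read(str(path)).get_structure(model=None)
        coords = np.asarray(stack.coord, dtype=float)
    elif suffix in (".dcd", ".xtc"):
        import mdtraj as md

        traj = md.load(str(path), top=_to_mdtraj_topology(topology))
        coords = np.asarray(traj.xyz, dtype=float) * 10.0  # nm -> A
    else:
        raise ParseError(f"unsupported trajectory format {suffix!r}")
    if coords.shape[1] != topology.n_atoms:
        raise ValueError(
            f"atom count mismatch: expected {topology.n_atoms}, "
            f"found {coords.shape[1]}"
        )
    return TrajectoryEnsemble(
        condition_id=condition_id,
        trajectories=[coords],
        frame_interval_ns=frame_interval_ns,
        topology=topology,
    )


def write_trajectory(ens: TrajectoryEnsemble, path: str | Path, trajectory: int = 0) -> None:
    """Write one trajectory of the ensemble as a multi-model PDB."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    top = ens.topology
    n = top.n_atoms
    xyz = ens.trajectories[trajectory]
    stack = struc.AtomArrayStack(xyz.shape[0], n)
    stack.coord = np.asarray(xyz, dtype=np.float32)
    stack.chain_id = np.array([a.chain_id for a in top.atoms])
    stack.res_id = np.array([a.res_id for a in top.atoms])
    stack.res_name = np.array([a.res_name for a in top.atoms])
    stack.atom_name = np.array([a.name for a in top.atoms])
    stack.element = np.array([a.element for a in top.atoms])
    stack.hetero = np.zeros(n, dtype=bool)
    pdbf = PDBFile()
    pdbf.set_structure(stack)
    pdbf.write(str(path))


def _to_mdtraj_topology(topology: Topology):
    import mdtraj as md

    mdtop = md.Topology()
    chains: dict[str, object] = {}
    residues: dict[tuple[str, int], object] = {}
    for a in topology.atoms:
        if a.chain_id not in chains:
            chains[a.chain_id] = mdtop.add_chain()
        rkey = (a.chain_id, a.res_id)
        if rkey not in residues:
            residues[rkey] = mdtop.add_residue(a.res_name, chains[a.chain_id], resSeq=a.res_id)
        try:
            elem = md.element.Element.getBySymbol(a.element.capitalize())
        except KeyError:
            elem = md.element.carbon
        mdtop.add_atom(a.name, elem, residues[rkey])
    return mdtop


# ---------------------------------------------------------------------------
# residue selection
# ---------------------------------------------------------------------------

def select_within(
    topology: Topology,
    coords: np.ndarray,
    center: tuple[str, int],
    cutoff_A: float,
    include: list[tuple[str, int]] | None = None,
    exclude: list[tuple[str, int]] | None = None,
    chains: list[str] | None = None,
) -> ResidueSelection:
    """Residues whose CA lies within ``cutoff_A`` of the center residue's CA.

    The distance rule is CA-to-CA on the single reference frame given.
    ``include``/``exclude`` overrides are applied after the geometric rule,
    which lets a published residue list be reproduced exactly.
    """
    if cutoff_A <= 0:
        raise ValueError("cutoff must be > 0")
    coords = np.asarray(coords, dtype=float)
    ci = topology.ca_index(*center)
    if ci < 0:
        raise ValueError(f"center residue {center} has no CA atom")
    c = coords[ci]
    selected: list[tuple[str, int]] = []
    for chain_id, res_id in topology.residues():
        if chains is not None and chain_id not in chains:
            continue
        ai = topology.ca_index(chain_id, res_id)
        if ai < 0:
            continue
        if np.linalg.norm(coords[ai] - c) <= cutoff_A:
            selected.append((chain_id, res_id))
    include = include or []
    exclude = set(exclude or [])
    for key in include:
        if key not in selected:
            selected.append(key)
    selected = [r for r in selected if r not in exclude]
    known = set(topology.residues())
    for key in selected:
        if key not in known:
            raise ValueError(f"selected residue {key} not in topology")
    prov = f"CA within {cutoff_A} A of {center[0]}{center[1]}"
    if include or exclude:
        prov += f" (+{len(include)} include, -{len(exclude)} exclude overrides)"
    return ResidueSelection(residues=selected, provenance=prov)


def selection_from_ranges(
    ranges: list[tuple[str, int, int]],
    exclude: list[tuple[str, int]] | None = None,
    provenance: str = "explicit ranges",
) -> ResidueSelection:
    """Build a selection from inclusive (chain, first, last) residue ranges."""
    exclude = set(exclude or [])
    residues = [
        (chain, r)
        for chain, lo, hi in ranges
        for r in range(lo, hi + 1)
        if (chain, r) not in exclude
    ]
    return ResidueSelection(residues=residues, provenance=provenance)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_manifest(out_dir: str | Path, config: RunConfig, inputs: list[str | Path]) -> Path:
    """Record config, seed and input hashes so a run is reproducible."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hashes = {}
    for p in inputs:
        p = Path(p)
        if p.is_file():
            hashes[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {"config": config.to_dict(), "seed": config.seed, "input_sha256": hashes}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
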