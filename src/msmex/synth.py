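"""Synthetic trajectory and H/D-exchange generators with analytic ground truth.

Downstream estimators (TICA, Markov state models, PCCA++ coarse-graining,
interaction statistics, exchange-curve fitting) are validated against data
whose generating process is known exactly.  The conformational generator is
a hidden discrete-time Markov chain over a small number of metastable
"archetype" structures; each frame is the archetype of the current latent
state plus temporally correlated Gaussian noise.  The archetypes emulate the
structural signatures of a peptide-receptor complex: a helix region that is
folded or unfolded, a side-chain "flip" dihedral, and a peptide that is
either bound or partially dissociated.

Ground truth exposed for every generated dataset: the stationary
distribution, all relaxation timescales (from the transition-matrix
eigenvalues), and the per-frame latent labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .io import Atom, Topology, TrajectoryEnsemble


# ---------------------------------------------------------------------------
# latent chain
# ---------------------------------------------------------------------------

@dataclass
class LatentChainSpec:
    """A discrete-time Markov chain at the trajectory frame interval."""

    transition_matrix: np.ndarray
    frame_interval_ns: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_matrix, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(T < -1e-15):
            raise ValueError("transition probabilities must be non-negative")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1")
        if not _is_irreducible(T):
            raise ValueError("chain is reducible")
        self.transition_matrix = T

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def stationary_distribution(self) -> np.ndarray:
        return stationary_distribution(self.transition_matrix)

    def relaxation_timescales_frames(self) -> np.ndarray:
        """Analytic implied timescales -1/ln lambda_i, descending, excluding
        the stationary eigenvalue."""
        lam = np.sort(np.real(np.linalg.eigvals(self.transition_matrix)))[::-1]
        lam = lam[1:]
        with np.errstate(divide="ignore"):
            ts = np.where(lam > 0, -1.0 / np.log(np.clip(lam, 1e-300, None)), 0.0)
        return ts


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Left Perron eigenvector of a row-stochastic matrix, normalized."""
    w, v = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _is_irreducible(T: np.ndarray) -> bool:
    n, labels = connected_components(T > 0, directed=True, connection="strong")
    return n == 1


def chain_from_populations(
    populations: np.ndarray,
    exchange_time_frames: float,
    frame_interval_ns: float = 1.0,
    seed: int = 0,
) -> LatentChainSpec:
    """Design a reversible chain with given stationary populations and a
    prescribed slowest relaxation time.

    A nearest-neighbour Metropolis chain on the ordered states has the
    requested stationary distribution by construction; uniformly rescaling
    its off-diagonal part (T = I + s (M - I)) shifts every eigenvalue
    towards 1 without touching detailed balance, so the slowest implied
    timescale can be set exactly.
    """
    pi = np.asarray(populations, dtype=float)
    if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("populations must be positive and sum to 1")
    if exchange_time_frames < 1:
        raise ValueError("exchange time must be >= 1 frame")
    n = len(pi)
    if n == 1:
        return LatentChainSpec(np.array([[1.0]]), frame_interval_ns, seed)
    M = np.zeros((n, n))
    for i in range(n):
        for j in (i - 1, i + 1):
            if 0 <= j < n:
                M[i, j] = 0.5 * min(1.0, pi[j] / pi[i])
        M[i, i] = 1.0 - M[i].sum()
    lam = np.sort(np.real(np.linalg.eigvals(M)))[::-1]
    mu2 = lam[1]
    target = np.exp(-1.0 / exchange_time_frames)
    s = (target - 1.0) / (mu2 - 1.0)
    T = np.eye(n) + s * (M - np.eye(n))
    if np.any(np.diag(T) < -1e-12):
        raise ValueError(
            f"requested exchange time {exchange_time_frames} frames is "
            "faster than this population profile supports"
        )
    return LatentChainSpec(np.clip(T, 0.0, 1.0) / np.clip(T, 0.0, 1.0).sum(axis=1, keepdims=True),
                           frame_interval_ns, seed)


def sample_latent_path(spec: LatentChainSpec, n_frames: int, seed: int | None = None) -> np.ndarray:
    """Sample a state sequence; the first state is drawn from the
    stationary distribution."""
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    T = spec.transition_matrix
    cum = np.cumsum(T, axis=1)
    pi = spec.stationary_distribution
    path = np.empty(n_frames, dtype=np.int32)
    path[0] = rng.choice(len(pi), p=pi)
    u = rng.random(n_frames - 1)
    for t in range(1, n_frames):
        path[t] = np.searchsorted(cum[path[t - 1]], u[t - 1], side="right")
    return path


# ---------------------------------------------------------------------------
# pseudo-protein geometry
# ---------------------------------------------------------------------------

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "CA-CB": 1.53,
         "CB-CG": 1.52, "CG-CD": 1.52}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.5,
          "N-CA-CB": 110.5, "CA-CB-CG": 114.0, "CB-CG-CD": 111.0}


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom d from a-b-c."""
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(dih),
        bond * np.sin(ang) * np.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi_deg, psi_deg, n_res: int) -> np.ndarray:
    """Build an N,CA,C,O backbone from phi/psi dihedrals (omega fixed trans).

    ``phi_deg``/``psi_deg`` may be scalars or per-residue arrays.  Returns an
    array of shape (n_res*4, 3): atoms ordered N, CA, C, O per residue.
    An ideal alpha-helix is (phi, psi) = (-57, -47); an extended strand is
    (-135, 135).
    """
    phi = np.broadcast_to(np.asarray(phi_deg, dtype=float), (n_res,))
    psi = np.broadcast_to(np.asarray(psi_deg, dtype=float), (n_res,))
    coords = np.zeros((n_res * 4, 3))
    # seed the first residue in the xy-plane
    N0 = np.array([0.0, 0.0, 0.0])
    CA0 = np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = np.deg2rad(_ANGLE["N-CA-C"])
    C0 = CA0 + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords[0], coords[1], coords[2] = N0, CA0, C0
    for i in range(n_res):
        N, CA, C = coords[4 * i], coords[4 * i + 1], coords[4 * i + 2]
        if i < n_res - 1:
            Nn = _place_atom(N, CA, C, _BOND["C-N"], _ANGLE["CA-C-N"], psi[i])
            CAn = _place_atom(CA, C, Nn, _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0)
            Cn = _place_atom(C, Nn, CAn, _BOND["CA-C"], _ANGLE["N-CA-C"], phi[i + 1])
            coords[4 * (i + 1)] = Nn
            coords[4 * (i + 1) + 1] = CAn
            coords[4 * (i + 1) + 2] = Cn
        # carbonyl O is anti to the next amide N around the CA-C axis
        coords[4 * i + 3] = _place_atom(N, CA, C, _BOND["C-O"], _ANGLE["CA-C-O"],
                                        psi[i] + 180.0)
    return coords


def _backbone_atoms(chain_id: str, n_res: int, res_name: str = "ALA") -> list[Atom]:
    from .constants import ELEMENT_MASSES

    atoms = []
    for r in range(1, n_res + 1):
        for name, elem in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            atoms.append(Atom(name=name, element=elem, res_id=r, res_name=res_name,
                              chain_id=chain_id, heavy=True,
                              mass=ELEMENT_MASSES[elem]))
    return atoms


@dataclass
class ArchetypeSet:
    """Per-latent-state reference structures sharing one topology."""

    topology: Topology
    coordinates: np.ndarray            # (n_states, n_atoms, 3), Angstrom
    noise_sigma_A: float = 0.10
    autocorr_time_frames: float = 2.0
    flip_dihedral_atoms: tuple[int, int, int, int] | None = None
    flipped_states: tuple[int, ...] = ()
    helix_residues: tuple[tuple[str, int], ...] = ()
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (states, atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError("archetype atom count does not match topology")
        if self.noise_sigma_A <= 0:
            raise ValueError("noise sigma must be > 0")

    @property
    def n_states(self) -> int:
        return self.coordinates.shape[0]


def pseudo_mhc2_archetypes(
    noise_sigma_A: float = 0.10,
    autocorr_time_frames: float = 2.0,
) -> ArchetypeSet:
    """Three-state pseudo peptide-receptor complex.

    State 0 ("ground"): receptor helix region folded, side chain in,
    peptide bound.  State 1 ("intermediate"): C-terminal half of the helix
    region unfolded.  State 2 ("rare"): helix region fully unfolded, side
    chain flipped out, peptide shifted away from the receptor (partial
    dissociation).  The states differ by many Angstroms in pairwise CA
    distances, far above the default positional noise.
    """
    n_a, n_b, n_p = 8, 24, 6
    helix_lo, helix_hi = 9, 20

    atoms: list[Atom] = []
    atoms += _backbone_atoms("A", n_a)
    # flip reporter side chain on A5: CB, CG, CD appended after chain A backbone
    from .constants import ELEMENT_MASSES
    for name in ("CB", "CG", "CD"):
        atoms.append(Atom(name=name, element="C", res_id=5, res_name="TRP",
                          chain_id="A", heavy=True, mass=ELEMENT_MASSES["C"]))
    atoms += _backbone_atoms("B", n_b)
    atoms += _backbone_atoms("P", n_p, res_name="GLY")
    # chain-A residue ids must stay ordered: the side-chain atoms of A5 come
    # after A8's backbone, so reorder chain A atom list by residue
    chain_a = [a for a in atoms if a.chain_id == "A"]
    chain_a.sort(key=lambda a: a.res_id)
    atoms = chain_a + [a for a in atoms if a.chain_id != "A"]
    topology = Topology(atoms=atoms, chain_roles={
        "A": "receptor-alpha", "B": "receptor-beta", "P": "peptide"})

    def chain_a_coords(chi_deg: float) -> np.ndarray:
        bb = build_backbone(-135.0, 135.0, n_a) + np.array([0.0, 14.0, 0.0])
        # side chain off residue 5: CB from N-CA-C frame, CG/CD extend it;
        # the flip dihedral is N-CA-CB-CG
        i0 = 4 * 4  # residue 5 backbone start in the unsorted backbone array
        N, CA, C = bb[i0], bb[i0 + 1], bb[i0 + 2]
        CB = _place_atom(C, N, CA, _BOND["CA-CB"], _ANGLE["N-CA-CB"], 122.0)
        CG = _place_atom(N, CA, CB, _BOND["CB-CG"], _ANGLE["CA-CB-CG"], chi_deg)
        CD = _place_atom(CA, CB, CG, _BOND["CG-CD"], _ANGLE["CB-CG-CD"], 180.0)
        out = np.zeros((n_a * 4 + 3, 3))
        # interleave to match the residue-sorted atom order
        k = 0
        for r in range(n_a):
            out[k:k + 4] = bb[4 * r:4 * r + 4]
            k += 4
            if r == 4:
                out[k], out[k + 1], out[k + 2] = CB, CG, CD
                k += 3
        return out

    def chain_b_coords(unfold_from: int | None) -> np.ndarray:
        phi = np.full(n_b, -57.0)
        psi = np.full(n_b, -47.0)
        if unfold_from is not None:
            sel = slice(unfold_from - 1, helix_hi)
            phi[sel] = -135.0
            psi[sel] = 135.0
        return build_backbone(phi, psi, n_b)

    def chain_p_coords(dissociated: bool) -> np.ndarray:
        bb = build_backbone(-135.0, 135.0, n_p) + np.array([2.0, -4.5, 0.0])
        if dissociated:
            bb = bb + np.array([0.0, -6.0, 3.0])
        return bb

    states = []
    for unfold_from, chi, diss in (
        (None, -60.0, False),          # ground
        (15, -60.0, False),            # intermediate: helix half unfolded
        (helix_lo, 175.0, True),       # rare: unfolded, flipped, dissociated
    ):
        states.append(np.concatenate([
            chain_a_coords(chi), chain_b_coords(unfold_from), chain_p_coords(diss)
        ]))
    coords = np.stack(states)

    flip_atoms = (
        int(topology.atom_indices("A", 5, "N")[0]),
        int(topology.atom_indices("A", 5, "CA")[0]),
        int(topology.atom_indices("A", 5, "CB")[0]),
        int(topology.atom_indices("A", 5, "CG")[0]),
    )
    return ArchetypeSet(
        topology=topology,
        coordinates=coords,
        noise_sigma_A=noise_sigma_A,
        autocorr_time_frames=autocorr_time_frames,
        flip_dihedral_atoms=flip_atoms,
        flipped_states=(2,),
        helix_residues=tuple(("B", r) for r in range(helix_lo, helix_hi + 1)),
        labels=("ground", "intermediate", "rare"),
    )


def emit_structures(
    path: np.ndarray,
    arch: ArchetypeSet,
    seed: int = 0,
    frame_interval_ns: float = 1.0,
    condition_id: str = "synthetic",
) -> TrajectoryEnsemble:
    """Emit coordinates for a latent state path.

    Frame t is the archetype of state_t plus an AR(1) Gaussian displacement
    (stationary std ``noise_sigma_A``, correlation time
    ``autocorr_time_frames``; per atom and per coordinate independent).
    """
    path = np.asarray(path)
    if path.max() >= arch.n_states or path.min() < 0:
        raise ValueError("path references states without an archetype")
    rng = np.random.default_rng(seed)
    n_frames = len(path)
    shape = (arch.topology.n_atoms, 3)
    sigma = arch.noise_sigma_A
    tau = arch.autocorr_time_frames
    rho = np.exp(-1.0 / tau) if tau > 0 else 0.0
    innov = np.sqrt(1.0 - rho * rho)
    eps = rng.standard_normal((n_frames,) + shape) * sigma
    if rho > 0:
        for t in range(1, n_frames):  # AR(1) recursion
            eps[t] = rho * eps[t - 1] + innov * eps[t]
    xyz = arch.coordinates[path] + eps
    return TrajectoryEnsemble(
        condition_id=condition_id,
        trajectories=[xyz],
        frame_interval_ns=frame_interval_ns,
        topology=arch.topology,
    )


# ---------------------------------------------------------------------------
# H/D exchange decay tables
# ---------------------------------------------------------------------------

@dataclass
class HDXResidueSpec:
    residue: str
    k_obs_per_min: float | None = None      # None for class-driven residues
    klass: str | None = None                # 'fast' | 'stable' | None


@dataclass
class HDXDecaySpec:
    """Ground truth for a synthetic exchange experiment.

    The default time grid mimics a back-to-back HSQC series: one spectrum
    every 35 min starting at the 35 min dead time, out to a 60 h horizon.
    """

    residues: list[HDXResidueSpec]
    time_grid_min: np.ndarray = field(
        default_factory=lambda: 35.0 * np.arange(1, 91))
    initial_sn: float = 100.0
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.time_grid_min, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        self.time_grid_min = t
        for r in self.residues:
            if (r.k_obs_per_min is None) == (r.klass is None):
                raise ValueError(
                    f"residue {r.residue}: give exactly one of k_obs or class")
            if r.klass is not None and r.klass not in ("fast", "stable"):
                raise ValueError(f"residue {r.residue}: unknown class {r.klass!r}")


def generate_hdx_table(spec: HDXDecaySpec) -> pd.DataFrame:
    """Emit per-residue decay observations as a long-form table.

    Columns: residue, time_min, sn.  "fast" residues sit at the noise floor
    from the first point; "stable" residues decay < 5% over the grid.
    """
    rng = np.random.default_rng(spec.seed)
    t = spec.time_grid_min
    horizon = t[-1]
    rows = []
    for r in spec.residues:
        if r.klass == "fast":
            # fully exchanged before the dead time: noise only, kept inside
            # the 3-sigma detection band by construction
            sn = np.clip(rng.normal(0.0, spec.noise_sigma, len(t)),
                         -2.5 * spec.noise_sigma, 2.5 * spec.noise_sigma)
        else:
            if r.klass == "stable":
                k = -np.log(0.98) / horizon   # 2% total decay
            else:
                k = float(r.k_obs_per_min)
            sn = spec.initial_sn * np.exp(-k * t)
            sn = sn + rng.normal(0.0, spec.noise_sigma, len(t))
        for ti, si in zip(t, sn):
            rows.append((r.residue, float(ti), float(si)))
    return pd.DataFrame(rows, columns=["residue", "time_min", "sn"])
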