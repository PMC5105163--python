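"""Per-metastable-state structural observables.

Every frequency here is a state-conditional mean of a per-frame indicator
(side-chain flip, residue contact, solvent contact, helicity), with a
1-sigma uncertainty from a trajectory-level bootstrap: trajectories are
resampled with replacement and the pooled state-conditional fraction is
recomputed per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TrajectoryEnsemble
from .msm import MetastableDecomposition


@dataclass
class FrameLabels:
    """Crisp metastable label per frame (-1 = frame in a pruned microstate)."""

    labels: list[np.ndarray]
    condition_id: str = "default"

    @property
    def unassigned_fraction(self) -> float:
        total = sum(len(l) for l in self.labels)
        bad = sum(int((l < 0).sum()) for l in self.labels)
        return bad / total if total else 0.0


def assign_frames(decomp: MetastableDecomposition,
                  dtrajs: list[np.ndarray],
                  condition_id: str = "default") -> FrameLabels:
    """Label every frame with the crisp metastable state of its microstate."""
    labels = [decomp.crisp[np.asarray(d)] for d in dtrajs]
    return FrameLabels(labels=labels, condition_id=condition_id)


@dataclass
class FlipSpec:
    """A four-atom dihedral with an angular interval that counts as
    'flipped-out'.  The interval is in degrees on (-180, 180] and may wrap
    (lo > hi means the arc passing through 180)."""

    atoms: tuple[int, int, int, int]
    flipped_interval_deg: tuple[float, float] = (120.0, -120.0)

    def __post_init__(self) -> None:
        if len(set(self.atoms)) != 4:
            raise ValueError("dihedral atoms must be distinct")


def dihedral_deg(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral angle(s) in degrees; inputs broadcast over frames."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - (b0 * b1n).sum(-1, keepdims=True) * b1n
    w = b2 - (b2 * b1n).sum(-1, keepdims=True) * b1n
    x = (v * w).sum(-1)
    y = (np.cross(b1n, v) * w).sum(-1)
    return np.degrees(np.arctan2(y, x))


def _in_interval(angle_deg: np.ndarray, lo: float, hi: float) -> np.ndarray:
    a = (angle_deg + 180.0) % 360.0 - 180.0
    if lo <= hi:
        return (a >= lo) & (a <= hi)
    return (a >= lo) | (a <= hi)


def _bootstrap_state_fraction(
    indicator: list[np.ndarray],
    labels: FrameLabels,
    states: list[int],
    n_boot: int,
    seed: int,
) -> dict[int, tuple[float, float]]:
    """Pooled per-state fraction of a per-frame indicator with a
    trajectory-resampling 1-sigma spread."""
    rng = np.random.default_rng(seed)
    n_traj = len(indicator)
    out: dict[int, tuple[float, float]] = {}
    flat_ind = np.concatenate(indicator)
    flat_lab = np.concatenate(labels.labels)
    for s in states:
        mask = flat_lab == s
        if mask.sum() == 0:
            out[s] = (np.nan, np.nan)
            continue
        point = float(flat_ind[mask].mean())
        reps = []
        for _ in range(n_boot):
            pick = rng.integers(0, n_traj, size=n_traj)
            num = den = 0.0
            for i in pick:
                m = labels.labels[i] == s
                num += indicator[i][m].sum()
                den += m.sum()
            if den:
                reps.append(num / den)
        sigma = float(np.std(reps)) if reps else np.nan
        out[s] = (point, sigma)
    return out


def flip_probability(
    ens: TrajectoryEnsemble,
    labels: FrameLabels,
    spec: FlipSpec,
    n_boot: int = 50,
    seed: int = 0,
) -> dict[int, tuple[float, float]]:
    """Per metastable state: probability of the flipped-out dihedral
    interval, +/- bootstrap sigma.  States with no frames report NaN."""
    i, j, k, l = spec.atoms
    indicator = []
    for xyz in ens.trajectories:
        ang = dihedral_deg(xyz[:, i], xyz[:, j], xyz[:, k], xyz[:, l])
        indicator.append(_in_interval(ang, *spec.flipped_interval_deg).astype(float))
    states = sorted({int(s) for l_ in labels.labels for s in np.unique(l_) if s >= 0})
    return _bootstrap_state_fraction(indicator, labels, states, n_boot, seed)


def _min_dist_indicator(xyz: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray,
                        cutoff: float) -> np.ndarray:
    """Per-frame flag: min distance between atom sets <= cutoff."""
    a = xyz[:, idx_a, :]
    b = xyz[:, idx_b, :]
    d2 = ((a[:, :, None, :] - b[:, None, :, :]) ** 2).sum(-1)
    return (d2.min(axis=(1, 2)) <= cutoff * cutoff).astype(float)


def contact_frequency(
    ens: TrajectoryEnsemble,
    labels: FrameLabels,
    group_a: list[tuple[str, int]],
    group_b: list[tuple[str, int]],
    cutoff_A: float = 4.0,
    n_boot: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """State-conditional contact frequency of each residue of group A with
    any residue of group B (heavy-atom minimum distance <= cutoff)."""
    top = ens.topology
    idx_b = np.concatenate([
        top.atom_indices(chain_id=c, res_id=r, heavy_only=True)
        for c, r in group_b
    ])
    if len(idx_b) == 0:
        raise ValueError("group B has no heavy atoms")
    rows = []
    states = sorted({int(s) for l_ in labels.labels for s in np.unique(l_) if s >= 0})
    for c, r in group_a:
        idx_a = top.atom_indices(chain_id=c, res_id=r, heavy_only=True)
        if len(idx_a) == 0:
            raise ValueError(f"residue {c}{r} has no heavy atoms")
        ind = [_min_dist_indicator(x, idx_a, idx_b, cutoff_A)
               for x in ens.trajectories]
        freq = _bootstrap_state_fraction(ind, labels, states, n_boot, seed)
        for s, (p, sd) in freq.items():
            rows.append((ens.condition_id, s, f"{c}{r}", p, sd))
    return pd.DataFrame(rows, columns=["condition", "state", "residue",
                                       "frequency", "sigma"])


def solvent_contact_frequency(
    ens: TrajectoryEnsemble,
    labels: FrameLabels,
    residues: list[tuple[str, int]],
    cutoff_A: float = 3.5,
    n_boot: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Water-contact frequency per residue and state.

    Contacts are counted to solvent oxygen atoms.  If the topology carries
    no solvent, a proxy is used and flagged: per frame the residue's
    exposure score 1/(1 + n_close), where n_close is the number of
    non-self heavy atoms within the cutoff — crowded residues score near
    0, fully exposed residues score 1.
    """
    top = ens.topology
    solvent_o = [i for i, a in enumerate(top.atoms)
                 if top.chain_roles.get(a.chain_id) == "solvent"
                 and a.element.upper() == "O"]
    proxy = len(solvent_o) == 0
    states = sorted({int(s) for l_ in labels.labels for s in np.unique(l_) if s >= 0})
    all_heavy = np.flatnonzero(top.heavy_mask())
    rows = []
    for c, r in residues:
        idx_a = top.atom_indices(chain_id=c, res_id=r, heavy_only=True)
        if proxy:
            others = np.setdiff1d(all_heavy, idx_a)
            ind = []
            for x in ens.trajectories:
                a = x[:, idx_a, :]
                b = x[:, others, :]
                d2 = ((a[:, :, None, :] - b[:, None, :, :]) ** 2).sum(-1)
                n_close = (d2 <= cutoff_A * cutoff_A).any(axis=1).sum(axis=1)
                ind.append(1.0 / (1.0 + n_close))
        else:
            ind = [_min_dist_indicator(x, idx_a, np.asarray(solvent_o), cutoff_A)
                   for x in ens.trajectories]
        freq = _bootstrap_state_fraction(ind, labels, states, n_boot, seed)
        for s, (p, sd) in freq.items():
            rows.append((ens.condition_id, s, f"{c}{r}", p, sd, proxy))
    return pd.DataFrame(rows, columns=["condition", "state", "residue",
                                       "frequency", "sigma", "proxy"])


def helicity_profile(
    ens: TrajectoryEnsemble,
    labels: FrameLabels,
    chain_id: str,
    res_range: tuple[int, int],
    on_cutoff_A: float = 3.5,
    n_boot: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Helical fraction per residue and state.

    Residue i counts as helical in a frame iff the backbone O(i)...N(i+4)
    distance is <= ``on_cutoff_A`` — the alpha-helical H-bond register,
    robust for pseudo-backbones.  Residues whose i+4 partner falls outside
    the chain are dropped with a warning.
    """
    top = ens.topology
    lo, hi = res_range
    chain_res = [r for c, r in top.residues() if c == chain_id]
    usable = [r for r in range(lo, hi + 1)
              if r in chain_res and (r + 4) in chain_res]
    if len(usable) < hi - lo + 1:
        warnings.warn(f"helicity range truncated to {len(usable)} residues")
    states = sorted({int(s) for l_ in labels.labels for s in np.unique(l_) if s >= 0})
    rows = []
    for r in usable:
        io = top.atom_indices(chain_id=chain_id, res_id=r, name="O")
        in4 = top.atom_indices(chain_id=chain_id, res_id=r + 4, name="N")
        if len(io) != 1 or len(in4) != 1:
            raise ValueError(f"residue {chain_id}{r}: backbone O/N missing")
        ind = []
        for x in ens.trajectories:
            d = np.linalg.norm(x[:, io[0]] - x[:, in4[0]], axis=-1)
            ind.append((d <= on_cutoff_A).astype(float))
        freq = _bootstrap_state_fraction(ind, labels, states, n_boot, seed)
        for s, (p, sd) in freq.items():
            rows.append((ens.condition_id, s, f"{chain_id}{r}", p, sd))
    return pd.DataFrame(rows, columns=["condition", "state", "residue",
                                       "helical_fraction", "sigma"])
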