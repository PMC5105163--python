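"""Pairwise interaction analysis between heavy-atom groups.

A pairwise interaction between two atom groups exists in a frame if they
form a hydrogen bond (donor-acceptor and hydrogen-acceptor distances plus
the donor-hydrogen-acceptor angle all within thresholds) or a heavy-atom
contact (minimum distance within a cutoff).  State-conditional interaction
frequencies are estimated by a two-level bootstrap: entire trajectories are
resampled with replacement while the microstate definition and the
microstate-to-metastable map stay fixed; the Markov model is re-estimated
on the resampled set and a fixed-size frame sample is drawn from the state
with stationary-weight-proportional probabilities.  Significant
differences between two states are flagged by a z-criterion on the
bootstrap means and standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import TrajectoryEnsemble, Topology
from .msm import MetastableDecomposition, count_transitions, estimate_reversible_msm


@dataclass
class InteractionCriteria:
    """Geometric thresholds; all comparisons are inclusive."""

    d_donor_acceptor_A: float = 3.5
    d_hydrogen_acceptor_A: float = 2.5
    angle_dha_deg: float = 120.0
    d_contact_A: float = 4.0

    def __post_init__(self) -> None:
        for v in (self.d_donor_acceptor_A, self.d_hydrogen_acceptor_A,
                  self.d_contact_A):
            if v <= 0:
                raise ValueError("distance thresholds must be positive")
        if not 0.0 < self.angle_dha_deg <= 180.0:
            raise ValueError("angle threshold must be in (0, 180]")


@dataclass
class AtomGroup:
    """Heavy-atom set with optional donor (heavy, attached H) pairs and
    acceptor atoms for hydrogen-bond detection."""

    name: str
    heavy: np.ndarray
    donors: list[tuple[int, int]] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.heavy = np.asarray(self.heavy, dtype=int)
        if len(self.heavy) == 0:
            raise ValueError(f"group {self.name!r} has no heavy atoms")


def residue_group(top: Topology, chain_id: str, res_id: int,
                  backbone_only: bool = False, sidechain_only: bool = False,
                  name: str | None = None) -> AtomGroup:
    """Build an AtomGroup for one residue; amide N-H donors and carbonyl O
    acceptors are registered when the atoms exist."""
    backbone_names = {"N", "CA", "C", "O", "H"}
    heavy, donors, acceptors = [], [], []
    h_by_name: dict[str, int] = {}
    atoms = [(i, a) for i, a in enumerate(top.atoms)
             if a.chain_id == chain_id and a.res_id == res_id]
    if not atoms:
        raise ValueError(f"residue {chain_id}{res_id} not in topology")
    for i, a in atoms:
        is_bb = a.name in backbone_names
        if backbone_only and not is_bb:
            continue
        if sidechain_only and is_bb:
            continue
        if a.heavy:
            heavy.append(i)
            if a.element.upper() == "O":
                acceptors.append(i)
        else:
            h_by_name[a.name] = i
    for i, a in atoms:
        if a.name == "N" and "H" in h_by_name and not sidechain_only:
            donors.append((i, h_by_name["H"]))
    return AtomGroup(name=name or f"{chain_id}{res_id}", heavy=heavy,
                     donors=donors, acceptors=acceptors)


def detect_interaction(
    coords: np.ndarray,
    group_a: AtomGroup,
    group_b: AtomGroup,
    criteria: InteractionCriteria | None = None,
) -> tuple[bool, str | None]:
    """Does a single frame show an interaction between the two groups?

    Returns (present, kind) with kind 'hbond', 'contact' or None; when
    both criteria fire, 'hbond' is reported.  Donor entries without an
    attached hydrogen are skipped with a warning.
    """
    criteria = criteria or InteractionCriteria()
    if set(group_a.heavy) & set(group_b.heavy):
        raise ValueError("interaction groups must be disjoint")
    if _any_hbond(coords, group_a, group_b, criteria) or \
       _any_hbond(coords, group_b, group_a, criteria):
        return True, "hbond"
    da = coords[group_a.heavy][:, None, :] - coords[group_b.heavy][None, :, :]
    if np.sqrt((da * da).sum(-1)).min() <= criteria.d_contact_A:
        return True, "contact"
    return False, None


def _any_hbond(coords: np.ndarray, donor_grp: AtomGroup, acc_grp: AtomGroup,
               c: InteractionCriteria) -> bool:
    for d_idx, h_idx in donor_grp.donors:
        if h_idx is None:
            warnings.warn(f"donor {d_idx} lacks an attached hydrogen; skipped")
            continue
        D, H = coords[d_idx], coords[h_idx]
        for a_idx in acc_grp.acceptors:
            A = coords[a_idx]
            if np.linalg.norm(D - A) > c.d_donor_acceptor_A:
                continue
            if np.linalg.norm(H - A) > c.d_hydrogen_acceptor_A:
                continue
            v1 = D - H
            v2 = A - H
            cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if ang >= c.angle_dha_deg:
                return True
    return False


@dataclass
class InteractionProfile:
    state: int
    pair_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    n_frames: int
    n_replicates: int
    n_skipped: int = 0


def _presence_per_frame(ens: TrajectoryEnsemble, pairs, criteria) -> list[np.ndarray]:
    """Per trajectory: (frames, n_pairs) boolean presence matrix."""
    out = []
    for xyz in ens.trajectories:
        pres = np.zeros((xyz.shape[0], len(pairs)), dtype=bool)
        for p, (ga, gb) in enumerate(pairs):
            for f in range(xyz.shape[0]):
                pres[f, p] = detect_interaction(xyz[f], ga, gb, criteria)[0]
        out.append(pres)
    return out


def interaction_frequencies(
    ens: TrajectoryEnsemble,
    dtrajs: list[np.ndarray],
    decomp: MetastableDecomposition,
    pairs: list[tuple[AtomGroup, AtomGroup]],
    criteria: InteractionCriteria | None = None,
    lag: int = 1,
    n_frames: int = 100,
    n_replicates: int = 50,
    seed: int = 0,
) -> dict[int, InteractionProfile]:
    """Bootstrapped state-conditional interaction frequencies.

    Per replicate: trajectories are resampled with replacement, the
    reversible Markov model is re-estimated on the resampled counts (the
    discretization and metastable map are fixed), ``n_frames`` frames are
    drawn from the state's frames with probability proportional to the
    updated stationary weight of each frame's microstate, and the presence
    fraction of every pair is recorded.  Reported are mean and SD over the
    replicates; replicates in which a state vanishes are skipped and
    counted.
    """
    criteria = criteria or InteractionCriteria()
    rng = np.random.default_rng(seed)
    presence = _presence_per_frame(ens, pairs, criteria)
    n_states_full = len(decomp.crisp)
    pair_names = [f"{a.name}|{b.name}" for a, b in pairs]
    n_traj = len(dtrajs)
    profiles: dict[int, InteractionProfile] = {}
    for state in range(decomp.n_meta):
        reps = []
        skipped = 0
        for _ in range(n_replicates):
            pick = rng.integers(0, n_traj, size=n_traj)
            # frames of this metastable state in the resampled trajectories
            frame_pres, frame_micro = [], []
            for i in pick:
                lab = decomp.crisp[np.asarray(dtrajs[i])]
                m = lab == state
                frame_pres.append(presence[i][m])
                frame_micro.append(np.asarray(dtrajs[i])[m])
            frame_pres = np.concatenate(frame_pres) if frame_pres else np.zeros((0, len(pairs)))
            frame_micro = np.concatenate(frame_micro) if frame_micro else np.zeros(0, int)
            if frame_pres.shape[0] == 0:
                skipped += 1
                continue
            try:
                C = count_transitions([dtrajs[i] for i in pick], n_states_full, lag)
                model = estimate_reversible_msm(C, lag_frames=lag)
                pi_full = np.zeros(n_states_full)
                pi_full[model.active_set] = model.stationary
                micro_counts = np.bincount(frame_micro, minlength=n_states_full)
                w = pi_full[frame_micro] / np.maximum(micro_counts[frame_micro], 1)
            except (ValueError, RuntimeError):
                w = np.ones(frame_pres.shape[0])
            if w.sum() <= 0:
                w = np.ones(frame_pres.shape[0])
            w = w / w.sum()
            draw = rng.choice(frame_pres.shape[0], size=n_frames, replace=True, p=w)
            reps.append(frame_pres[draw].mean(axis=0))
        if not reps:
            raise ValueError(f"metastable state {state} has no frames")
        reps = np.asarray(reps)
        profiles[state] = InteractionProfile(
            state=state, pair_names=pair_names,
            mean=reps.mean(axis=0), sd=reps.std(axis=0, ddof=0),
            n_frames=n_frames, n_replicates=len(reps), n_skipped=skipped)
    return profiles


def significant_differences(
    profile_a: InteractionProfile,
    profile_b: InteractionProfile,
    z: float = 2.0,
) -> list[dict]:
    """Pairs whose frequency differs between two states by more than
    z * sqrt(SD_a^2 + SD_b^2), sorted by effect size (descending)."""
    if profile_a.pair_names != profile_b.pair_names:
        raise ValueError("profiles cover different pair lists")
    delta = profile_a.mean - profile_b.mean
    pooled = np.sqrt(profile_a.sd ** 2 + profile_b.sd ** 2)
    flagged = []
    for p, name in enumerate(profile_a.pair_names):
        if abs(delta[p]) > z * pooled[p]:
            flagged.append({
                "pair": name,
                "mean_a": float(profile_a.mean[p]),
                "mean_b": float(profile_b.mean[p]),
                "delta": float(delta[p]),
                "pooled_sd": float(pooled[p]),
            })
    flagged.sort(key=lambda d: -abs(d["delta"]))
    return flagged
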