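import numpy as np
import pytest

from msmex import observables as obs
from msmex import synth
from msmex.io import TrajectoryEnsemble
from msmex.msm import MetastableDecomposition
from conftest import make_atom
from msmex.io import Topology


def _decomp(crisp, n_meta=2):
    crisp = np.asarray(crisp)
    return MetastableDecomposition(
        n_meta=n_meta, memberships=np.eye(n_meta)[np.clip(crisp, 0, None)],
        crisp=crisp, populations=np.ones(n_meta) / n_meta,
        active_set=np.flatnonzero(crisp >= 0))


class TestAssignFrames:
    def test_crisp_labels_follow_microstates(self):
        decomp = _decomp([0, 0, 1, 1])
        dtrajs = [np.array([0, 1, 2, 3, 2, 0])]
        labels = obs.assign_frames(decomp, dtrajs)
        np.testing.assert_array_equal(labels.labels[0], [0, 0, 1, 1, 1, 0])
        assert labels.unassigned_fraction == 0.0

    def test_pruned_microstates_unassigned(self):
        decomp = _decomp([0, -1, 1, 1])
        labels = obs.assign_frames(decomp, [np.array([0, 1, 1, 2])])
        assert labels.unassigned_fraction == pytest.approx(0.5)

    def test_label_fractions_match_populations_on_synthetic_data(self):
        spec = synth.chain_from_populations(np.array([0.7, 0.3]), 10.0)
        path = synth.sample_latent_path(spec, 100_000, seed=0)
        decomp = _decomp([0, 1])
        labels = obs.assign_frames(decomp, [path])
        frac1 = np.mean(labels.labels[0] == 1)
        assert abs(frac1 - 0.3) < 0.02


class TestFlipProbability:
    def _flip_ens(self, flipped_flags):
        # 4 atoms; dihedral 0 (in) or 180 (out) controlled per frame
        top = Topology(atoms=[make_atom(n, 1, "A") for n in
                              ("N", "CA", "CB", "CG")])
        frames = []
        for f in flipped_flags:
            p0 = [0.0, 1.0, 0.0]
            p1 = [0.0, 0.0, 0.0]
            p2 = [1.0, 0.0, 0.0]
            p3 = [1.0, -1.0, 0.0] if f else [1.0, 1.0, 0.0]
            frames.append([p0, p1, p2, p3])
        xyz = np.asarray(frames, dtype=float)
        return TrajectoryEnsemble("c", [xyz], 1.0, top)

    def test_direct_fraction(self):
        flags = [True] * 16 + [False] * 84
        ens = self._flip_ens(flags)
        labels = obs.FrameLabels([np.zeros(100, dtype=int)])
        spec = obs.FlipSpec(atoms=(0, 1, 2, 3),
                            flipped_interval_deg=(90.0, -90.0))
        out = obs.flip_probability(ens, labels, spec, n_boot=10, seed=0)
        assert out[0][0] == pytest.approx(0.16)

    def test_all_flipped(self):
        ens = self._flip_ens([True] * 20)
        labels = obs.FrameLabels([np.zeros(20, dtype=int)])
        spec = obs.FlipSpec(atoms=(0, 1, 2, 3),
                            flipped_interval_deg=(90.0, -90.0))
        p, sd = obs.flip_probability(ens, labels, spec, n_boot=10, seed=0)[0]
        assert p == 1.0
        assert sd == 0.0

    def test_recovers_archetype_flip_states(self):
        arch = synth.pseudo_mhc2_archetypes()
        spec_chain = synth.chain_from_populations(np.array([0.5, 0.3, 0.2]), 20.0)
        path = synth.sample_latent_path(spec_chain, 4000, seed=1)
        ens = synth.emit_structures(path, arch, seed=1)
        labels = obs.FrameLabels([path])
        fspec = obs.FlipSpec(atoms=arch.flip_dihedral_atoms,
                             flipped_interval_deg=(120.0, -120.0))
        out = obs.flip_probability(ens, labels, fspec, n_boot=10, seed=0)
        assert out[0][0] < 0.02          # ground state: flipped in
        assert out[2][0] > 0.98          # rare state: flipped out


class TestContactFrequency:
    def _two_residue_ens(self, n_contact, n_total):
        atoms = [make_atom("CA", 1, "A"), make_atom("CA", 1, "B")]
        top = Topology(atoms=atoms, chain_roles={"A": "receptor-alpha",
                                                 "B": "peptide"})
        xyz = np.zeros((n_total, 2, 3))
        xyz[:, 1, 0] = 10.0
        xyz[:n_contact, 1, 0] = 3.0
        return TrajectoryEnsemble("c", [xyz], 1.0, top)

    def test_always_and_never(self):
        labels = obs.FrameLabels([np.zeros(10, dtype=int)])
        always = self._two_residue_ens(10, 10)
        df = obs.contact_frequency(always, labels, [("A", 1)], [("B", 1)],
                                   cutoff_A=4.0, n_boot=5, seed=0)
        assert df["frequency"].iloc[0] == 1.0
        never = self._two_residue_ens(0, 10)
        df = obs.contact_frequency(never, labels, [("A", 1)], [("B", 1)],
                                   cutoff_A=4.0, n_boot=5, seed=0)
        assert df["frequency"].iloc[0] == 0.0

    def test_matches_brute_force_enumeration(self):
        ens = self._two_residue_ens(7, 10)
        labels = obs.FrameLabels([np.zeros(10, dtype=int)])
        df = obs.contact_frequency(ens, labels, [("A", 1)], [("B", 1)],
                                   cutoff_A=4.0, n_boot=5, seed=0)
        # brute force over frames
        brute = np.mean([
            np.linalg.norm(ens.trajectories[0][f, 0] - ens.trajectories[0][f, 1]) <= 4.0
            for f in range(10)])
        assert df["frequency"].iloc[0] == pytest.approx(brute) == pytest.approx(0.7)


class TestSolventContact:
    def test_proxy_path_flagged_without_solvent(self):
        atoms = [make_atom("CA", 1, "A"), make_atom("CA", 2, "A")]
        top = Topology(atoms=atoms, chain_roles={"A": "receptor-alpha"})
        xyz = np.zeros((4, 2, 3))
        xyz[:, 1, 0] = 20.0
        ens = TrajectoryEnsemble("c", [xyz], 1.0, top)
        labels = obs.FrameLabels([np.zeros(4, dtype=int)])
        df = obs.solvent_contact_frequency(ens, labels, [("A", 1)], n_boot=5,
                                           seed=0)
        assert bool(df["proxy"].iloc[0])
        assert df["frequency"].iloc[0] == 1.0   # isolated residue fully exposed

    def test_water_shell_half_the_time(self):
        atoms = [make_atom("CA", 1, "A"), make_atom("O", 1, "W", element="O",
                                                    res_name="HOH")]
        top = Topology(atoms=atoms, chain_roles={"A": "receptor-alpha",
                                                 "W": "solvent"})
        xyz = np.zeros((10, 2, 3))
        xyz[:, 1, 0] = 30.0
        xyz[:5, 1, 0] = 2.5          # water close in half the frames
        ens = TrajectoryEnsemble("c", [xyz], 1.0, top)
        labels = obs.FrameLabels([np.zeros(10, dtype=int)])
        df = obs.solvent_contact_frequency(ens, labels, [("A", 1)],
                                           cutoff_A=3.5, n_boot=5, seed=0)
        assert not bool(df["proxy"].iloc[0])
        assert df["frequency"].iloc[0] == pytest.approx(0.5)


class TestHelicityProfile:
    def _ens_from_backbones(self, frames_phi_psi, n_res=12):
        top = Topology(
            atoms=[make_atom(n, r, "B", e) for r in range(1, n_res + 1)
                   for n, e in zip(("N", "CA", "C", "O"), ("N", "C", "C", "O"))],
            chain_roles={"B": "receptor-beta"})
        frames = [synth.build_backbone(phi, psi, n_res)
                  for phi, psi in frames_phi_psi]
        return TrajectoryEnsemble("c", [np.asarray(frames)], 1.0, top)

    def test_ideal_helix_is_fully_helical(self):
        ens = self._ens_from_backbones([(-57.0, -47.0)] * 3)
        labels = obs.FrameLabels([np.zeros(3, dtype=int)])
        df = obs.helicity_profile(ens, labels, "B", (1, 8), n_boot=5, seed=0)
        assert np.all(df["helical_fraction"].to_numpy() == 1.0)

    def test_extended_chain_is_not_helical(self):
        ens = self._ens_from_backbones([(-135.0, 135.0)] * 3)
        labels = obs.FrameLabels([np.zeros(3, dtype=int)])
        df = obs.helicity_profile(ens, labels, "B", (1, 8), n_boot=5, seed=0)
        assert np.all(df["helical_fraction"].to_numpy() == 0.0)

    def test_half_helical_mixture(self):
        ens = self._ens_from_backbones([(-57.0, -47.0)] * 5 + [(-135.0, 135.0)] * 5)
        labels = obs.FrameLabels([np.zeros(10, dtype=int)])
        df = obs.helicity_profile(ens, labels, "B", (1, 8), n_boot=5, seed=0)
        assert np.all(df["helical_fraction"].to_numpy() == pytest.approx(0.5))

    def test_range_truncated_with_warning(self):
        ens = self._ens_from_backbones([(-57.0, -47.0)] * 2)
        labels = obs.FrameLabels([np.zeros(2, dtype=int)])
        with pytest.warns(UserWarning, match="truncated"):
            df = obs.helicity_profile(ens, labels, "B", (1, 12), n_boot=5,
                                      seed=0)
        assert df["residue"].nunique() == 8
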