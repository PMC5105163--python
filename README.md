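# msmex

Markov-state-model analysis of conformational plasticity in peptide–MHC
class II (pMHCII) complexes — and, more generally, in any receptor–ligand
system where rare, exchange-competent conformations matter.

Stable pMHCII complexes exchange their bound peptide either intrinsically
or through the catalyst HLA-DM, and the propensity for the catalysed
pathway correlates with the population of a rare (~1–2%), partially
unfolded metastable conformation that ordinary structural methods miss.
Quantifying such states from molecular dynamics requires a chain of
estimators whose statistics must be trustworthy at the percent level:

1. **Featurization** — all pairwise Cα distances over a residue selection
   (e.g. residues within 15 Å of a groove residue).
2. **TICA** — time-lagged independent component analysis: solve
   `C̄_τ v = λ (C₀ + εI) v` and keep the slowest components.
3. **Discretization** — k-means (k = 100 by default) with *one* shared
   center set across all simulated conditions, so mutants are compared on
   identical microstates.
4. **Reversible MSM** — maximum-likelihood transition matrix under
   detailed balance (`π_i T_ij = π_j T_ji`), by fixed-point iteration on
   symmetric edge weights; validated by implied timescales
   `t_i(τ) = −τ/ln λ_i(τ)` and a Chapman–Kolmogorov test.
5. **PCCA++** — coarse-graining into metastable states; populations `Π_m`
   give free energies `ΔG_m = −RT ln(Π_m/Π_ref)` and cross-condition
   shifts `ΔΔG = RT ln(fold)`; inter-state rates are 1/MFPT.
6. **Uncertainty** — trajectory-level bootstrap with the discretization
   and metastable map held fixed; 1σ intervals are the 15.87/84.13
   percentiles.

Around the MSM core the package provides per-state structural observables
(side-chain flip probability, contact/solvent-contact frequencies, helicity
profiles), a bootstrapped pairwise-interaction analyser with a z-score
significance rule, NMR H/D-exchange quantitation in the EX2 limit
(`K_ex = k_obs/k_int`, protection factor `P = K_ex⁻¹`,
`ΔG_op/cl = −RT ln K_ex`), the center-of-mass / inertia-tensor simulation
restraint with analytic gradients, and a synthetic-data generator whose
hidden Markov chain makes every downstream estimate checkable against
analytic ground truth.

## Worked example

Plant a three-state system with a 1.6% rare state and an exchange time of
100 frames, then run the full pipeline on 50 trajectories × 10,000 frames:

```python
from msmex import msm, pipeline

study = pipeline.run_synthetic_study(
    populations=(0.776, 0.208, 0.016), exchange_time_frames=100.0,
    n_traj=50, frames_per_traj=10_000, seed=1)

print(study["estimates"]["populations"])        # per latent state
print(study["estimates"]["free_energies_kj"])   # kJ/mol vs ground state
print(msm.delta_delta_g(28.0, 310.0))           # fold-change identity
```

With seed 1 this prints a rare-state population of 1.43% (truth 1.6%,
within one bootstrap σ of 0.17%), free energies of 0 / 3.34 / 10.29 kJ/mol
against the analytic 0 / 3.39 / 10.00 kJ/mol, a slowest implied timescale
of 91.6 frames (truth 100), and the analytic identity
`RT ln 28 = 8.59 kJ/mol` at 310 K (similarly `RT ln 200 = 13.66 kJ/mol`) —
the free-energy shifts that correspond to 28-fold and 200-fold
stabilizations of a rare state.

The same stages are reachable from the shell:

```bash
msmex study --seed 1 --n-traj 20 --frames-per-traj 5000 --out out/
msmex synth-hdx --seed 2 --out out/            # synthetic decay table
msmex hdx --decays out/hdx_decays.tsv --noise 2.0 --out out/
msmex restraint-demo --out out/
```

Every run writes a `manifest.json` (config, seed, input hashes).

## Layout

| module               | contents                                              |
|----------------------|-------------------------------------------------------|
| `msmex.io`           | topology/trajectory/selection data model, PDB/DCD/XTC I/O, run config + manifests |
| `msmex.synth`        | hidden-chain trajectory generator, backbone builder, HDX decay generator |
| `msmex.features`     | pairwise Cα distances, TICA                           |
| `msmex.msm`          | k-means, reversible MSM, implied timescales, CK test, PCCA++, thermodynamics, rates, bootstrap, seed-structure sampling |
| `msmex.observables`  | flip/contact/solvent/helicity per-state observables   |
| `msmex.interactions` | pairwise interaction detection, bootstrapped frequencies, significance |
| `msmex.hdx`          | EX2 decay fitting, protection factors, ΔG, CSP        |
| `msmex.restraints`   | COM / inertia-tensor restraints, periodic-image monitor, demo dynamics |

See `docs/methods.md` for the models, conventions and numerical choices.
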