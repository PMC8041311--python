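# slidescope

Coarse-grained simulation and analysis of protein diffusion along
double-stranded DNA, built to distinguish the two linear-diffusion
mechanisms of DNA-binding proteins:

- **sliding** — rotation-coupled translation tracking the major groove,
  with a theta/Z slope of about −2π/34 ≈ −0.18 rad/Å (one full turn per
  34 Å helical pitch);
- **hopping** — translation decoupled from rotation (slope ≈ 0), via
  micro-dissociation and rebinding.

The package provides:

| module               | what it does |
|----------------------|--------------|
| `structure_io`       | PDB parsing, one-bead-per-residue coarse-graining with native-topology terms (bonds/angles/dihedrals from the input conformation, heavy-atom native contacts), charge assignment, ideal B-DNA builder (3 beads/nucleotide, Z-aligned), plain-text model files |
| `forcefield`         | native-topology potential (harmonic bonds/angles, dihedral series, 12-10 contacts, 12th-power repulsion) plus Debye–Hückel electrostatics with salt-dependent screening; analytic forces (numba-compiled kernels) |
| `simulator`          | BAOAB Langevin dynamics of the protein around a static DNA in reduced units (k_B = 1, unit masses), reflecting X/Y walls, Z-periodic minimum image; HDF5 trajectories + XYZ export |
| `coupling_analysis`  | unwrapped COM azimuth vs axial position, OLS theta/Z slope with classification (sliding / hopping / intermediate), sliding-origin MSD and diffusion coefficients (slope = 2dD) |
| `variant_engine`     | charge-neutralization variants: recognition-helix combinatorial scans (C(n,k) designs) and the three PCNA trimer designs; simulate-and-classify scans over variants × salt |
| `synthetic_data`     | download-free fixtures: toy charged helices (with PDB text), stochastic trajectories with prescribed coupling slope / diffusion coefficient / noise, canonical fixture suite with a ground-truth manifest |

## Quick start (CLI)

```sh
# coarse-grain a protein (4.5 Å heavy-atom contact cutoff)
slidescope build --pdb protein.pdb --chain A --cutoff 4.5 --out model.cg

# 100-bp ideal B-DNA on the Z axis
slidescope dna --length 100 --out dna.cg

# Langevin run at 0.01 M salt
slidescope run --model model.cg --dna dna.cg --salt 0.01 --steps 1e6 \
    --seed 7 --out traj.h5

# coupling slope, mechanism, diffusion coefficient
slidescope analyze --traj traj.h5 --selection protein --fit-window 1:200

# recognition-helix variant scan
slidescope scan --model model.cg --dna dna.cg --helix-residues 2,5,9,12,16,19 \
    --k-retained 5 --salts 0.01 --replicates 10 --out scan.tsv

# synthetic fixture suite with ground-truth manifest
slidescope fixtures --out fixtures/
```

Python API mirrors the CLI; see module docstrings. A minimal end-to-end
run:

```python
from slidescope import (ToyProteinSpec, make_toy_protein, build_bdna,
                        SimulationConfig, run_simulation,
                        angular_trace, fit_theta_z)

protein, _ = make_toy_protein(ToyProteinSpec(
    n_residues=20, charges={2: 1, 5: 1, 9: 1, 12: 1, 16: 1, 19: 1}))
dna = build_bdna("GCAT" * 13)
cfg = SimulationConfig(n_steps=500_000, stride=500, salt_molar=0.01,
                       seed=1, dna_bead_radius=4.0,
                       elec_cutoff=40.0, rep_cutoff_factor=3.0)
traj = run_simulation(protein, dna, cfg)
print(fit_theta_z(angular_trace(traj), burn_in=0.2))
```

## Units and conventions

- Distances in Å, charges in elementary charges, energies in kcal/mol
  treated as reduced units with k_B = 1 (the published reduced temperature
  0.4 is k_B·T in these units).
- The DNA axis is Z; the duplex's helical sense is chosen so a
  groove-tracking trajectory moving toward +Z accumulates negative
  azimuth, i.e. sliding gives a slope of −0.18 rad/Å.
- Because of the coarse-grained representation, the effective salt
  concentration may correspond to a severalfold higher value than in an
  atomistic description; concentration is exposed as the user-facing knob.

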