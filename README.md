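# polycg

Residue-level (one bead per amino acid) coarse-grained simulation and
analysis of arginine-rich peptide binding to folded transport proteins.

The package builds Cα bead models from structures and sequences, implements
an implicit-solvent force field (two-branch 8–6 hydrophobic/hydrophilic
potential, screened Coulomb electrostatics with a distance-dependent
dielectric, 8–6 cation–π potentials between R/K and F/Y/W, a stiff elastic
network for folded regions), propagates them with BAOAB Langevin dynamics in
periodic boxes, and computes contact statistics (time-averaged contact
counts, per-residue contact probabilities, contact-site calls, overlap with
annotated binding sites) plus the charge-parameter correlation
`x = NCPR − f·M/Rg` with a 1-D optimization of the free parameter `f`.

## Layout

| module | contents |
|---|---|
| `polycg.model` | `CGModel` / `Descriptors` data types, JSON serialization |
| `polycg.model_builder` | PDB/FASTA parsing, bead property assignment, disorder marking, elastic network, polyPR chains, NCPR/dipole/Rg descriptors |
| `polycg.force_field` | all pair potentials, pair classification, energy/forces (numpy reference route + numba fast route) |
| `polycg.simulator` | Langevin/NVE integrator, complex placement, cell-list neighbor search, trajectories |
| `polycg.contact_analysis` | contact counts, normalization, 3-block SEM, contact probabilities, `Nshared` |
| `polycg.charge_correlation` | charge parameter, OLS fits, `f` optimization |
| `polycg.synthetic_data` | toy folded components with controlled charge/dipole, annotation fixtures, synthetic correlation datasets |

Units: nm, ps, kJ/mol, elementary charge e; masses in g/mol.

## CLI

```sh
polycg make-fixtures --out-dir fixtures --seed 0   # toy inputs, no downloads
polycg build structure.pdb --out model.json        # PDB -> bead model
polycg describe --model model.json                 # NCPR / dipole / Rg
polycg simulate --model fixtures/rangap_like.json --polypr 20 \
    --steps 100000 --salt 100 --seed 1 --out traj.npz
polycg analyze --trajectory traj.npz --model fixtures/rangap_like.json \
    --annotations fixtures/rangap_like_annotations.tsv --out-prefix contacts
polycg fit --dataset fixtures/correlation_dataset.tsv
```

## Notes

- The per-residue hydrophobic strengths in `src/polycg/data/hydropathy.tsv`
  are an input table (see its header); swap the file or pass a custom table
  to recalibrate.
- The default nonbonded truncation is 2.5 nm with the energy shifted to zero
  at the cutoff; pass `ForceFieldParams(cutoff=None)` for untruncated
  potentials.
- Trajectories save to `.npz` (scratch use) or plain-text XYZ.
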