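# allostate

Analysis toolkit for the LDH/MalDH enzyme superfamily: normalized residue
numbering and catalytic-site signature mapping on phylogenies,
conformational-landscape geometry on structural ensembles (inter-atom
distance distributions, helix-orientation angle, R-like/T-like state
calls, side-chain substates, mobile-loop state), and enzyme-kinetics
rate-law fitting — together with seeded synthetic generators that stand
in for MD trajectories and raw assay data with known ground truth.

## Modules

| module | what it does |
|---|---|
| `allostate.numbering` | map any family sequence onto normalized (family-standard) residue numbers via global alignment to a packaged reference profile |
| `allostate.signatures` | classify residues at positions 68/102/199/246/250 as LDH-like / MalDH-like and export iTOL-style tree annotations |
| `allostate.structure_io` | conformer ensembles from multi-model PDB; resolve (chain, normalized residue, atom name) to coordinates |
| `allostate.geometry` | Kabsch superposition, distance series, X-aligned reference and the signed helix-orientation angle (Cα167→Cα181 projected on the X–Z plane) |
| `allostate.landscape` | KDE distance distributions with peak detection, 2D (θ, d) landscapes with R/T-like labels, χ1/χ2 substate clustering, loop open/closed calls |
| `allostate.kinetics` | Michaelis–Menten / allosteric sigmoidal / substrate-inhibition fits, AICc model selection, kcat/Km |
| `allostate.synthetic_data` | seeded generators: dimer ensembles with planted states, saturation curves, toy family FASTA/Newick fixtures |
| `allostate.crystal` | loop-distance report for deposited crystal structures |
| `allostate.cli` | `allostate` command with run manifests |

## CLI

Every subcommand writes its outputs plus a `manifest.json` capturing the
configuration, thresholds, seeds and input checksums.

```sh
allostate simulate ensemble --seed 1 --out runs/ens        # synthetic dimer + truth
allostate simulate kinetics --seed 1 --out runs/kin        # synthetic saturation data
allostate kinetics-fit --csv runs/kin/saturation.csv --model auto --seed 7 --out runs/fit
allostate number --fasta seqs.fa --reference builtin:ldh --out maps/
allostate signatures --fasta family.fa --tree family.nwk --out anno/
allostate distances --pdb traj.pdb --pairs A/171:CG-A/141:CA --out out/
allostate helix-angle --pdb traj.pdb --reference ref.pdb --chain A --out out/
allostate landscape --pdb traj.pdb --reference ref.pdb --chain A --out out/
allostate substates --pdb traj.pdb --chain A --out out/
allostate loopstate --pdb traj.pdb --chain A --out out/
```

Structure subcommands default to `--numbering identity` (author residue
numbers taken as normalized numbers, appropriate for the synthetic
fixtures and for entries deposited in the family-standard numbering);
pass `--numbering builtin:ldh` to attach alignment-based numbering.

## Notes

- The packaged reference profile is an engineered scaffold carrying the
  family's catalytic constellation at its standard normalized positions
  on a fixed pseudo-random background (see the JSON header). Mapping of
  *real* family sequences should be validated against a published
  correspondence table; disagreements are flagged, never overridden.
- R/T-like state thresholds and loop open/closed bands are declared
  heuristics (defaults documented in `landscape.py`) and are always
  embedded in run manifests.
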