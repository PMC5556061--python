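# sh3kit

Tools for characterising SH3-domain polyproline ligand recognition:

- **`sh3kit.motif`** — consensus-motif model for the eight-position ligand
  core `(A/P)₋₁ P₀ x₁ K₂ P₃ x₄ (L/R)₅ Z₆` (Z = L/P/S/T): core location in
  peptides, position-frequency-matrix construction with two-pass anchoring,
  log-odds (bit) window scoring, and exhaustive sequence matching.
- **`sh3kit.scan`** — proteome-wide FASTA scanning for motif hits, with
  N-terminal flank-acidity annotation, weighted ranking and TSV round trips.
- **`sh3kit.structure`** — multi-MODEL PDB ensemble loading, geometric
  interface-contact detection (H-bonds, salt bridges, nonpolar contacts),
  per-ensemble occupancy tables with conserved/moderate/transient/weak
  bands, binding-pocket classification, Kabsch backbone RMSD, and relative
  chemical-shift-perturbation tables.
- **`sh3kit.energetics`** — per-residue interaction-energy decomposition in
  the single-trajectory MM-GBSA style: Coulomb + 12-6 van der Waals cross
  terms (1-4 scaling folded in), HCT generalized-Born polar solvation with
  Debye-Hückel salt screening, and a Shrake-Rupley SASA nonpolar term.
  Parameters ship as an editable heavy-atom table (`sh3kit.params`); this
  is a functional-form engine, not a force-field reproduction.
- **`sh3kit.binding`** — one-site ITC forward simulation (displaced-volume
  injection model) and fitting (single and joint maximum-likelihood over
  replicates), inverse-variance pooling, four-parameter-logistic
  displacement curves and EC50 fitting, relative-affinity ratios, plus a
  fixture registry of ground-truth binding parameters.
- **`sh3kit.msa`** — alignment column analysis: reference-residue→column
  mapping, column composition profiles, allowed-set filtering, and
  position-probability matrices.
- **`sh3kit.synth`** — seeded generators for every input class (peptide
  libraries, proteomes with planted motifs, jittered complex ensembles
  built on a hand-made toy template, titrations, displacement curves), each
  emitting a machine-readable truth table.

## CLI

All functionality is reachable through the `sh3kit` entry point:

```bash
sh3kit simulate peptides --seed 1 --out out/            # synthetic inputs
sh3kit build-pfm --peptides out/peptides.fasta --out pfm.tsv
sh3kit scan --fasta proteome.fasta --pfm pfm.tsv --out hits.tsv
sh3kit simulate ensemble --seed 2 --n 40 --noise 0.3 --out ens/
sh3kit interface --pdb ens/ensemble.pdb --ligand-chain B --out iface/
sh3kit energize --pdb ens/ensemble.pdb --ligand-chain B --out decomp.tsv
sh3kit simulate itc --seed 1 --n 3 --out itc/
sh3kit fit-itc itc/itc_PPPKPPRL_rep*.tsv --out fit.json
sh3kit simulate elisa --seed 1 --out elisa/
sh3kit fit-elisa elisa/elisa_clone1_rep*.tsv
sh3kit msa-column --alignment sh3.fasta --ref my_domain --resnum 17 --allowed ED
```

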