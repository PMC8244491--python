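# gpcrscreen

A toolkit for ligand discovery scaffolding around G protein-coupled
receptors (GPCRs) without experimental structures. It provides:

- **Biophysical template selection** for homology modelling: Eisenberg-scale
  moving-window hydrophobicity profiles, per-helix sum-of-squared-difference
  (SSD) correspondence scoring, global sequence identity and query coverage,
  ligand-profile comparison by Tanimoto similarity, and orthosteric-pocket
  comparison with a substitution matrix over Ballesteros-Weinstein (BW)
  positions.
- **Atomic-property-field (APF) pharmacophore screening**: seven-channel
  per-atom property assignment (H-bond donor/acceptor, sp2, lipophilicity,
  size, electronegativity, charge), Gaussian 3D property grids, a consensus
  pharmacophore with a 75% channel-inclusion rule, rigid-body superposition
  with random restarts, and library screening by pseudo-energy score.
- **MM-GBSA aggregation arithmetic**: snapshot averaging of
  `G_complex - G_receptor - G_ligand` and component decomposition
  (`dG_gas = dE_vdW + dE_Ele`, `dG_bind = dG_gas + dE_Sol`).
- **Synthetic fixtures**: deterministic generators for 7-TM receptor
  sequences with controlled hydrophobicity and for actives/decoys ligand
  benchmarks, so every stage is testable offline.

## CLI

All subcommands accept `--config` (YAML overriding the defaults in
`gpcrscreen.pipeline.DEFAULT_CONFIG`), `--seed` and `--out-dir`, and write
deterministic CSV/JSON reports plus a `manifest.json` with input hashes.

```bash
gpcrscreen profile target.fasta target.tm.tsv --out-dir out/
gpcrscreen select-template target.fasta target.tm.tsv candidates.tsv \
    --target-ligands known_ligands.smi --out-dir out/
gpcrscreen ligand-sim target.smi template.smi --out-dir out/
gpcrscreen pocket-score a.fasta a.tm.tsv b.fasta b.tm.tsv --matrix BLOSUM62
gpcrscreen apf-build actives.sdf --out-dir out/
gpcrscreen apf-screen actives.sdf library.sdf --seed 0 --out-dir out/
gpcrscreen mmgbsa energies.csv --out-dir out/
gpcrscreen make-fixtures --n-actives 10 --n-decoys 90 --seed 0 --out-dir out/
```

Input formats: FASTA sequences; TM annotation TSV (`helix  start  end
anchor`, 1-based inclusive, anchor = the residue labelled x.50); candidate
metadata TSV (`pdb_id  receptor_name  resolution  state  fasta  tm_tsv
ligand_smiles`); SMILES (one per line, id after whitespace) or SDF V2000
with 3D coordinates; energy CSV in either per-snapshot
(`complex_id,frame,G_com,G_rec,G_lig`) or per-complex component
(`complex_id,dE_vdW,dE_Ele,dE_Sol`) layout.

## Notes on conventions

- Global alignment: Needleman-Wunsch, BLOSUM62, gap open 10 / extend 0.5
  (matrix units); identity excludes terminal-gap columns; coverage is the
  fraction of target residues aligned opposite template residues.
- Hydrophobicity window: 11 residues, full windows only; SSD per residue
  divides by the number of paired profile positions; per-residue SSD above
  0.1 flags poor correspondence.
- Helix tethering pairs centre residues (centre = floor((L+1)/2), 1-based)
  and extends symmetrically, dropping overhangs.
- APF kernel: isotropic Gaussian (default sigma 1.0 A, spacing 0.5 A,
  padding 3.0 A, per-axis 3.5-sigma truncation), per-ligand-count
  normalisation; scores are on this kernel's scale, so screening thresholds
  are configurable rather than fixed.
- Fingerprints: RDKit Morgan radius-2 folded to 881 bits (recorded in
  output metadata as the scheme actually computed).
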