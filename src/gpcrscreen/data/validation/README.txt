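Optional validation-tier data (not bundled)
===========================================

The validation-tier checks (pocket substitution scores against published
GPCR structures, OR1A2/OR1A1 sequence identity) require third-party
reference data that this package does not redistribute. To enable them,
place the following files in this directory (or point the CLI at them):

  or1a2.fasta        UniProt Q9Y585 full sequence
  or1a1.fasta        UniProt Q9P1Q5 full sequence
  <pdbid>.fasta      template receptor sequences (1U19, 2RH1, 5IU4, 5ZKC)
  <name>.tm.tsv      TM annotation tables (columns: helix, start, end,
                     anchor) for each sequence, with the x.50 anchor
                     residues taken from a generic-numbering resource
                     such as GPCRdb
  gpcrtm.txt         the GPCRtm substitution matrix in NCBI matrix
                     format (Rios et al. 2015, BMC Bioinformatics 16:206)

Tests gated on these files are skipped when the files are absent.
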