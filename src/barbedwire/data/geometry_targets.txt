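# Protein backbone covalent geometry targets (Engh & Huber style values).
# One line per term: name  ideal  sigma
# Bond lengths in Angstrom, bond angles in degrees.
# Junction-spanning terms (C-N, CA-C-N, C-N-CA) are stored on the later
# residue of the peptide bond by the analysis code.
N-CA     1.459   0.020
CA-C     1.525   0.026
C-N      1.336   0.023
C-O      1.229   0.019
N-CA-C   111.0   2.8
CA-C-N   117.2   2.2
C-N-CA   121.7   2.5
CA-C-O   120.1   2.1
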