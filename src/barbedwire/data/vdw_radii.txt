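# United-atom van der Waals radii (Angstrom) used for heavy-atom contact
# analysis.  Carbons and nitrogens that carry implicit hydrogens get
# slightly inflated radii so that heavy-atom gaps approximate
# hydrogenated-surface gaps.
# atom-class  radius
C        1.70
C_UNI    1.90
N        1.60
N_UNI    1.70
O        1.52
S        1.80
P        1.80
DEFAULT  1.80
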