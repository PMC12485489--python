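# Coarse polygonal (axis-aligned box) Ramachandran allowed-region map.
# A (phi, psi) pair is an outlier when it falls inside NO box of its
# residue class.  This is a deliberately coarse stand-in for contour
# tables from the validation literature: it accepts the canonical
# alpha, beta, polyproline-II and left-handed-alpha regions with margin
# and rejects the unprotein-like upper-right quadrant.  Replaceable via
# config with a higher-fidelity table in the same format.
# class  phi_min phi_max psi_min psi_max
general  -180 -30 -100  180
general  -180 -30 -180 -150
general    40  80   10   80
gly      -180 -30 -100  180
gly      -180 -30 -180 -150
gly        30 180 -180  100
gly        30 180  150  180
pro      -110 -40  100  180
pro      -110 -40 -180 -160
pro      -110 -40  -75   30
prepro   -180 -30 -100  180
prepro   -180 -30 -180 -150
prepro     40  80   10   80
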