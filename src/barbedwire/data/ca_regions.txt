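# Coarse allowed-region map for CA-trace pseudo-dihedrals, used as a
# lightweight proxy for CA-geometry validation.  A residue's incoming
# pseudo-dihedral d_in = dihedral(CA[i-2], CA[i-1], CA[i], CA[i+1]) and
# outgoing d_out = dihedral(CA[i-1], CA[i], CA[i+1], CA[i+2]) must fall
# inside at least one box below, otherwise the residue is a CA-geometry
# outlier.  Boxes accept canonical helix, extended/strand, polyproline-II
# and the transitions between helix and extended geometry.  Authentic
# per-residue outlier calls from external validation software can be
# imported instead (see validation_flags).
# din_min din_max dout_min dout_max
  20   80   20   80
-180 -100 -180 -100
-180 -100  100  180
 100  180 -180 -100
 100  180  100  180
-130  -40 -130  -40
  20   80 -180 -100
  20   80  100  180
-180 -100   20   80
 100  180   20   80
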