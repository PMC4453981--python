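# Residue volume parameter sets, in units of 1e-3 nm^3 per residue.
# Only the consensus unhydrated crystal-structure set is wired into
# modelling; further sets may be added under new labels and selected
# explicitly.
consensus_crystal:
  ALA: 97.1
  ARG: 192.9
  ASN: 127.4
  ASP: 125.3
  CYS: 112.4
  GLN: 147.3
  GLU: 148.0
  GLY: 68.2
  HIS: 158.3
  ILE: 170.1
  LEU: 182.8
  LYS: 184.5
  MET: 176.0
  PHE: 203.9
  PRO: 129.0
  SER: 103.3
  THR: 129.0
  TRP: 228.9
  TYR: 202.3
  VAL: 142.3
  FUC: 160.8
  GAL: 166.8
  GLC: 171.9
  MAN: 170.8
  NAG: 222.0
  NGA: 232.9
  SIA: 326.3
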