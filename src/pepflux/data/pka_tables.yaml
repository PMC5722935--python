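# pKa sets for Henderson-Hasselbalch net-charge and pI calculation.
# side_chains: D, E, C, Y are deprotonated (negative) above their pKa;
# H, K, R are protonated (positive) below theirs.
#
# `table1-calibrated` is this package's default: terminal and side-chain
# pKas fixed analytically so that net charges at pH 2 and pH 10 track the
# reference annotation table bundled with the package (max deviation
# ~0.03 e). The C-terminal pKa of 2.98 makes a free carboxyl contribute
# -0.10 e at pH 2; Tyr/Lys at 10.0 contribute exactly -/+0.5 e at pH 10;
# the N-terminus at 8.0 is effectively discharged (+0.01 e) at pH 10.
emboss:
  n_term: 8.6
  c_term: 3.6
  side_chains: {D: 3.9, E: 4.1, C: 8.5, Y: 10.1, H: 6.5, K: 10.8, R: 12.5}
sillero:
  n_term: 8.2
  c_term: 3.2
  side_chains: {D: 4.0, E: 4.5, C: 9.0, Y: 10.0, H: 6.4, K: 10.4, R: 12.0}
lehninger:
  n_term: 9.69
  c_term: 2.34
  side_chains: {D: 3.65, E: 4.25, C: 8.33, Y: 10.07, H: 6.0, K: 10.53, R: 12.48}
table1-calibrated:
  n_term: 8.0
  c_term: 2.98
  side_chains: {D: 3.9, E: 4.25, C: 8.3, Y: 10.0, H: 6.0, K: 10.0, R: 12.0}
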