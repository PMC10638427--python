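# Sample coding of the E. coli replication-protein AP-MS screen:
# 8 SPA-tagged baits x 3 growth conditions x 3 biological replicates,
# plus per condition one untagged-strain control (control1, resin
# binders) and one heterologous-tag control (control2, tag binders),
# each in triplicate. Run codes are the MaxQuant datafile names.
conditions: [LB_log, LB_ON, M9_ac_ON]
baits:
  DiaA:
    LB_log: [E1, I4, X6]
    LB_ON: [I5, P1, X7]
    M9_ac_ON: [I6, T3, X5]
  DnaA:
    LB_log: [F2, U6, U7]
    LB_ON: [F1, P2, X12]
    M9_ac_ON: [E3, I7, X11]
  DnaB:
    LB_log: [G4, W3, W4]
    LB_ON: [G6, W5, W6]
    M9_ac_ON: [G2, W1, W2]
  DnaG:
    LB_log: [H1, J5, U9]
    LB_ON: [C7, F6, H2]
    M9_ac_ON: [F7, H3, X15]
  Hda:
    LB_log: [C5, U8, X9]
    LB_ON: [C6, P3, X10]
    M9_ac_ON: [I3, T4, X8]
  HolD:
    LB_log: [U1, U2, U3]
    LB_ON: [F8, U11, X4]
    M9_ac_ON: [X1, X2, X3]
  NrdB:
    LB_log: [W7, W8, W9]
    LB_ON: [F10, J4, U13]
    M9_ac_ON: [F9, J3, T10]
  SeqA:
    LB_log: [F4, X13, X14]
    LB_ON: [F3, P4, U12]
    M9_ac_ON: [F5, T1, T2]
controls:
  control1:
    label: MG1655
    LB_log: [T7, T8, T9]
    LB_ON: [P5, U10, X17]
    M9_ac_ON: [T5, T6, X16]
  control2:
    label: mVenus-SPA
    LB_log: [S1, S2, S3]
    LB_ON: [O9, R4, R5]
    M9_ac_ON: [R1, R2, R3]
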