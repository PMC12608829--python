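# Urea/urease on a pH-sensitive capacitive sensor in dilute phosphate buffer.
# Buffer couple: H2PO4- / HPO4^2- (pKa 7.21 at 25 C).
# Acid product:  H2CO3 / HCO3-   (pKa 6.35); base product: NH4+ / NH3 (pKa 9.25).
# One bicarbonate and two ammonium units are produced per urea hydrolysed.
label: pbs_urea
buffer:
  c_wb_mM: 0.33
  pKa_w: 7.21
  pH_bulk: 7.4
  kbar_w: 1.0
products:
  n_a: 1
  pKa_a: 6.35
  n_b: 2
  pKa_b: 9.25
transport:
  kbar_h: 1.0
  D_cm2_s: 9.3e-5    # urea diffusion constant
  l_cm: 1.0          # active layer length
  t_cm: 1.0e-7       # active layer thickness
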