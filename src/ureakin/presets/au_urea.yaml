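# Urea/urease in a 10x-diluted artificial-urine-like matrix adjusted to pH 7.4.
# The multicomponent matrix is modelled as an effective single phosphate-like
# buffer; the effective concentration (2 mM) reflects the phosphate content of
# common artificial-urine recipes after tenfold dilution.  The strong contrast
# with PBS in practice is carried by the (much smaller) fitted kbar_V, not by
# the buffer block.
label: au_urea
buffer:
  c_wb_mM: 2.0
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
  D_cm2_s: 9.3e-5
  l_cm: 1.0
  t_cm: 1.0e-7
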