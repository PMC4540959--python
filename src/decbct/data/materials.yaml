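# Built-in material definitions.
#
# Each entry gives either a chemical formula (mass fractions are derived from
# standard atomic masses) or an explicit composition map {element: mass fraction}.
# Densities are common reference values (g/cm^3) and may be overridden when a
# material is loaded.
water:
  formula: H2O
  density: 1.000
graphite:
  formula: C
  density: 1.700
aluminum:
  formula: Al
  density: 2.699
silicon:
  formula: Si
  density: 2.330
pmma:
  formula: C5H8O2
  density: 1.190
polyethylene:
  formula: C2H4
  density: 0.930
air:
  # dry air, simplified to N/O only (argon folded into N, fractions renormalized)
  composition: {N: 0.7682, O: 0.2318}
  density: 0.0012
vacuum:
  composition: {}
  density: 0.0
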