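# Canonical parameter tables and assay presets.
models:
  minimal:
    a: 1.0          # activation u^2 v coefficient (v -> u)
    b: 1.0          # inactivation rate (u -> v)
    Dm: 0.01        # activator (membrane) diffusivity
    Dc: 1.0         # substrate (cytosol) diffusivity
  indirect:
    a: 1.0
    b: 1.0
    c: 0.01         # u -> v_i
    d: 1.0          # v_i -> v
    Dm: 0.01
    Dc: 1.0
    Dvi: 1.0        # indirect-substrate diffusivity
  mechanistic:
    k1a: 10.0       # 1/s BemGEF_c -> BemGEF_m
    k1b: 10.0       # 1/s BemGEF_m -> BemGEF_c
    k2a: 0.16       # 1/(uM s) GEF-catalysed activation
    k2b: 1.75       # 1/s GAP-mediated inactivation
    k3: 0.35        # 1/(uM s) BemGEF42-catalysed activation
    k4a: 10.0       # 1/(uM s) BemGEF_m + Cdc42T binding
    k4b: 10.0       # 1/s complex dissociation
    k5a: 36.0       # 1/s Cdc42D_c -> Cdc42D_m
    k5b: 0.65       # 1/s Cdc42D_m -> Cdc42D_c
    k7: 10.0        # 1/(uM s) BemGEF_c + Cdc42T binding
    Dm: 0.0025      # um^2/s membrane diffusion
    Dc: 10.0        # um^2/s cytoplasmic diffusion
    eta: 0.01       # membrane/cytoplasm volume ratio
  mechanistic_nfb:
    k1a: 10.0
    k1b: 10.0
    k2a: 0.16
    k2b: 0.35       # slower GAP activity in the negative-feedback variant
    k3: 0.35
    k4a: 10.0
    k4b: 10.0
    k5a: 36.0
    k5b: 0.65
    k7: 10.0
    k8max: 0.0063   # 1/(uM s) max GEF phosphorylation rate
    k8n: 6.0
    k8h: 10.0       # uM
    k9max: 0.0044   # 1/s max dephosphorylation rate
    k9n: 6.0
    k9h: 0.003      # uM
    Dm: 0.0025
    Dc: 10.0
    eta: 0.01

presets:
  minimal_compete:        # sub-saturation pair: larger peak wins
    model: minimal
    amounts: [0.6, 1.0]
    expected: competition
  minimal_coexist:        # saturated pair: negligible flux, peaks persist
    model: minimal
    amounts: [2.0, 4.0]
    expected: coexistence
  nfb_compete:
    model: mechanistic_nfb
    amounts: [0.6, 1.2]
    expected: competition
  nfb_equalize:
    model: mechanistic_nfb
    amounts: [1.0, 2.0]
    expected: equalization
  indirect_compete:
    model: indirect
    amounts: [0.6, 0.9]
    expected: competition
  indirect_equalize_low:
    model: indirect
    amounts: [0.8, 1.2]
    expected: equalization
  indirect_equalize_high:
    model: indirect
    amounts: [1.2, 1.8]
    expected: equalization
  phase_sweep_small:      # coarse outcome sweep over Dvi x total amount
    model: indirect
    Dvi_values: [0.01, 0.3, 1.0, 3.0]
    amount_values: [1.0, 1.5, 2.0, 3.0]
    split: [0.6, 0.4]
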