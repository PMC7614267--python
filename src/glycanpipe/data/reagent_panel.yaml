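# Exoglycosidase / chemical reagent panel.
#
# Each reagent is a combination of specificity primitives implemented by the
# digestion engine; `partial` marks reagents with incomplete conversion
# (intermediate products are admissible observations) and `weight` is the
# evidence weight its digestion consistency contributes during annotation.
reagents:
  - name: fucm
    display: "alpha-1,2-fucosidase (microbial FUCM)"
    primitives: [bisect_a2_fucosidase]
    partial: false
    weight: 2.0
  - name: coffee-agal
    display: "coffee bean alpha-galactosidase"
    primitives: [alpha_galactosidase]
    partial: false
    weight: 2.0
  - name: nidulans-bgal
    display: "A. nidulans beta-galactosidase"
    primitives: [corefuc_beta_galactosidase]
    partial: false
    weight: 2.0
  - name: niger-bgal
    display: "A. niger beta-galactosidase"
    primitives: [corefuc_beta_galactosidase, bisect_beta_galactosidase]
    partial: false
    weight: 2.0
  - name: hex4
    display: "C. elegans HEX-4 beta-N-acetylgalactosaminidase"
    primitives: [galnac_hexosaminidase]
    partial: false
    weight: 2.0
  - name: jackbean-hex
    display: "jack bean beta-N-acetylhexosaminidase"
    primitives: [broad_hexosaminidase]
    partial: false
    weight: 2.0
  - name: chitinase
    display: "S. plicatus chitinase"
    primitives: [chito_chain_hexosaminidase]
    # all its removals are admissible-only, which already yields every
    # intermediate as a product
    partial: false
    weight: 0.5
  - name: jackbean-man
    display: "jack bean alpha-mannosidase"
    primitives: [broad_alpha_mannosidase]
    partial: false
    weight: 2.0
  - name: a23-man
    display: "Xanthomonas alpha-1,2/3-mannosidase"
    primitives: [a23_alpha_mannosidase]
    partial: false
    weight: 2.0
  - name: pce
    display: "S. pneumoniae phosphorylcholine esterase"
    primitives: [pc_esterase]
    partial: true
    weight: 2.0
  - name: hf
    display: "hydrofluoric acid"
    # complete for alpha-1,3-fucose and PC; partial only for the
    # alpha-1,2-(methyl)fucose on the bisecting galactose, which the
    # hf_bisect_fucose primitive models as admissible-only removals
    primitives: [hf_a3_fucose, hf_pc, hf_bisect_fucose]
    partial: false
    weight: 2.0
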