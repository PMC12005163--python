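# Stepwise ladder over species x context (divergence/polymorphism)
# partitions, ignoring gene class.  Species labels follow the three-way
# Drosophila comparison convention: mel, ana, wil.  Tiers are a
# reconstruction of the published stepwise procedure.
name: species-context
models:
  g1:
    - {param: all}
  s2_mel:
    - {param: mel, species: mel}
    - {param: anawil}
  s2_ana:
    - {param: ana, species: ana}
    - {param: melwil}
  s2_wil:
    - {param: wil, species: wil}
    - {param: melana}
  c2_ctx:
    - {param: div, context: divergence}
    - {param: poly}
  s3_species:
    - {param: mel, species: mel}
    - {param: ana, species: ana}
    - {param: wil}
  m3_melctx:
    - {param: mel.div, species: mel, context: divergence}
    - {param: mel.poly, species: mel}
    - {param: anawil}
  m3_anawilctx:
    - {param: mel, species: mel}
    - {param: anawil.div, context: divergence}
    - {param: anawil.poly}
  c3_divmel:
    - {param: mel.div, species: mel, context: divergence}
    - {param: anawil.div, context: divergence}
    - {param: poly}
  c3_divana:
    - {param: ana.div, species: ana, context: divergence}
    - {param: melwil.div, context: divergence}
    - {param: poly}
  c3_divwil:
    - {param: wil.div, species: wil, context: divergence}
    - {param: melana.div, context: divergence}
    - {param: poly}
  c3_polymel:
    - {param: div, context: divergence}
    - {param: mel.poly, species: mel}
    - {param: anawil.poly}
  c3_polyana:
    - {param: div, context: divergence}
    - {param: ana.poly, species: ana}
    - {param: melwil.poly}
  c3_polywil:
    - {param: div, context: divergence}
    - {param: wil.poly, species: wil}
    - {param: melana.poly}
  m4_bothctx:
    - {param: mel.div, species: mel, context: divergence}
    - {param: mel.poly, species: mel}
    - {param: anawil.div, context: divergence}
    - {param: anawil.poly}
  m4_melctx_species:
    - {param: mel.div, species: mel, context: divergence}
    - {param: mel.poly, species: mel}
    - {param: ana, species: ana}
    - {param: wil}
  m5_splitdiv:
    - {param: mel.div, species: mel, context: divergence}
    - {param: mel.poly, species: mel}
    - {param: ana.div, species: ana, context: divergence}
    - {param: wil.div, species: wil, context: divergence}
    - {param: anawil.poly}
  m5_splitpoly:
    - {param: mel.div, species: mel, context: divergence}
    - {param: mel.poly, species: mel}
    - {param: anawil.div, context: divergence}
    - {param: ana.poly, species: ana}
    - {param: wil.poly, species: wil}
  m6_full:
    - {param: mel.div, species: mel, context: divergence}
    - {param: mel.poly, species: mel}
    - {param: ana.div, species: ana, context: divergence}
    - {param: ana.poly, species: ana}
    - {param: wil.div, species: wil, context: divergence}
    - {param: wil.poly, species: wil}
tiers:
  - [g1]
  - [s2_mel, s2_ana, s2_wil, c2_ctx]
  - [s3_species, m3_melctx, m3_anawilctx, c3_divmel, c3_divana, c3_divwil,
     c3_polymel, c3_polyana, c3_polywil]
  - [m4_bothctx, m4_melctx_species]
  - [m5_splitdiv, m5_splitpoly]
  - [m6_full]
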