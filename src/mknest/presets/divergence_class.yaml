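# Divergence x gene-class ladder: given per-species divergence and
# polymorphism structure, does the piRNA machinery need its own
# divergence modifier, shared or per species?  Polymorphism keeps one
# modifier per species throughout; background (other-gene) divergence is
# per species throughout.
name: divergence-class
models:
  dc_base:
    - {param: div.pi, context: divergence, gene_class: piRNA}
    - {param: mel.div.o, species: mel, context: divergence}
    - {param: ana.div.o, species: ana, context: divergence}
    - {param: wil.div.o, species: wil, context: divergence}
    - {param: mel.poly, species: mel}
    - {param: ana.poly, species: ana}
    - {param: wil.poly}
  dc_pimel:
    - {param: mel.div.pi, species: mel, context: divergence, gene_class: piRNA}
    - {param: anawil.div.pi, context: divergence, gene_class: piRNA}
    - {param: mel.div.o, species: mel, context: divergence}
    - {param: ana.div.o, species: ana, context: divergence}
    - {param: wil.div.o, species: wil, context: divergence}
    - {param: mel.poly, species: mel}
    - {param: ana.poly, species: ana}
    - {param: wil.poly}
  dc_piana:
    - {param: ana.div.pi, species: ana, context: divergence, gene_class: piRNA}
    - {param: melwil.div.pi, context: divergence, gene_class: piRNA}
    - {param: mel.div.o, species: mel, context: divergence}
    - {param: ana.div.o, species: ana, context: divergence}
    - {param: wil.div.o, species: wil, context: divergence}
    - {param: mel.poly, species: mel}
    - {param: ana.poly, species: ana}
    - {param: wil.poly}
  dc_piwil:
    - {param: wil.div.pi, species: wil, context: divergence, gene_class: piRNA}
    - {param: melana.div.pi, context: divergence, gene_class: piRNA}
    - {param: mel.div.o, species: mel, context: divergence}
    - {param: ana.div.o, species: ana, context: divergence}
    - {param: wil.div.o, species: wil, context: divergence}
    - {param: mel.poly, species: mel}
    - {param: ana.poly, species: ana}
    - {param: wil.poly}
  dc_pifull:
    - {param: mel.div.pi, species: mel, context: divergence, gene_class: piRNA}
    - {param: ana.div.pi, species: ana, context: divergence, gene_class: piRNA}
    - {param: wil.div.pi, species: wil, context: divergence, gene_class: piRNA}
    - {param: mel.div.o, species: mel, context: divergence}
    - {param: ana.div.o, species: ana, context: divergence}
    - {param: wil.div.o, species: wil, context: divergence}
    - {param: mel.poly, species: mel}
    - {param: ana.poly, species: ana}
    - {param: wil.poly}
tiers:
  - [dc_base]
  - [dc_pimel, dc_piana, dc_piwil]
  - [dc_pifull]
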