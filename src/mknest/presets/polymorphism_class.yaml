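# Polymorphism x gene-class ladder, the mirror image of the divergence
# ladder: divergence keeps one modifier per species; the piRNA
# machinery's polymorphism modifier starts shared across species and is
# refined species by species.
name: polymorphism-class
models:
  pc_base:
    - {param: poly.pi, context: polymorphism, gene_class: piRNA}
    - {param: mel.poly.o, species: mel, context: polymorphism}
    - {param: ana.poly.o, species: ana, context: polymorphism}
    - {param: wil.poly.o, species: wil, context: polymorphism}
    - {param: mel.div, species: mel}
    - {param: ana.div, species: ana}
    - {param: wil.div}
  pc_pimel:
    - {param: mel.poly.pi, species: mel, context: polymorphism, gene_class: piRNA}
    - {param: anawil.poly.pi, context: polymorphism, gene_class: piRNA}
    - {param: mel.poly.o, species: mel, context: polymorphism}
    - {param: ana.poly.o, species: ana, context: polymorphism}
    - {param: wil.poly.o, species: wil, context: polymorphism}
    - {param: mel.div, species: mel}
    - {param: ana.div, species: ana}
    - {param: wil.div}
  pc_piana:
    - {param: ana.poly.pi, species: ana, context: polymorphism, gene_class: piRNA}
    - {param: melwil.poly.pi, context: polymorphism, gene_class: piRNA}
    - {param: mel.poly.o, species: mel, context: polymorphism}
    - {param: ana.poly.o, species: ana, context: polymorphism}
    - {param: wil.poly.o, species: wil, context: polymorphism}
    - {param: mel.div, species: mel}
    - {param: ana.div, species: ana}
    - {param: wil.div}
  pc_piwil:
    - {param: wil.poly.pi, species: wil, context: polymorphism, gene_class: piRNA}
    - {param: melana.poly.pi, context: polymorphism, gene_class: piRNA}
    - {param: mel.poly.o, species: mel, context: polymorphism}
    - {param: ana.poly.o, species: ana, context: polymorphism}
    - {param: wil.poly.o, species: wil, context: polymorphism}
    - {param: mel.div, species: mel}
    - {param: ana.div, species: ana}
    - {param: wil.div}
  pc_pifull:
    - {param: mel.poly.pi, species: mel, context: polymorphism, gene_class: piRNA}
    - {param: ana.poly.pi, species: ana, context: polymorphism, gene_class: piRNA}
    - {param: wil.poly.pi, species: wil, context: polymorphism, gene_class: piRNA}
    - {param: mel.poly.o, species: mel, context: polymorphism}
    - {param: ana.poly.o, species: ana, context: polymorphism}
    - {param: wil.poly.o, species: wil, context: polymorphism}
    - {param: mel.div, species: mel}
    - {param: ana.div, species: ana}
    - {param: wil.div}
tiers:
  - [pc_base]
  - [pc_pimel, pc_piana, pc_piwil]
  - [pc_pifull]
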