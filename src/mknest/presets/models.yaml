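# Stand-alone model specifications for fitting, summary statistics and
# bootstrap.  "full12" is the saturated species x context x class
# partition; "selected9" is the structure chosen by the divergence and
# polymorphism class ladders (piRNA divergence: mel alone plus shared
# ana+wil; piRNA polymorphism shared across species; per-species
# background modifiers).
models:
  full12:
    - {param: mel.div.pi, species: mel, context: divergence, gene_class: piRNA}
    - {param: mel.div.o, species: mel, context: divergence}
    - {param: mel.poly.pi, species: mel, context: polymorphism, gene_class: piRNA}
    - {param: mel.poly.o, species: mel, context: polymorphism}
    - {param: ana.div.pi, species: ana, context: divergence, gene_class: piRNA}
    - {param: ana.div.o, species: ana, context: divergence}
    - {param: ana.poly.pi, species: ana, context: polymorphism, gene_class: piRNA}
    - {param: ana.poly.o, species: ana, context: polymorphism}
    - {param: wil.div.pi, species: wil, context: divergence, gene_class: piRNA}
    - {param: wil.div.o, species: wil, context: divergence}
    - {param: wil.poly.pi, species: wil, context: polymorphism, gene_class: piRNA}
    - {param: wil.poly.o, species: wil, context: polymorphism}
  selected9:
    - {param: mel.div.pi, species: mel, context: divergence, gene_class: piRNA}
    - {param: anawil.div.pi, context: divergence, gene_class: piRNA}
    - {param: mel.div.o, species: mel, context: divergence}
    - {param: ana.div.o, species: ana, context: divergence}
    - {param: wil.div.o, species: wil, context: divergence}
    - {param: poly.pi, context: polymorphism, gene_class: piRNA}
    - {param: mel.poly.o, species: mel, context: polymorphism}
    - {param: ana.poly.o, species: ana, context: polymorphism}
    - {param: wil.poly.o, species: wil, context: polymorphism}
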