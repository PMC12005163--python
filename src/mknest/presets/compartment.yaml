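# Compartment ladder: divergence only, two species (mel, ana), asking
# whether nuclear and cytoplasmic components of the piRNA machinery need
# distinct divergence modifiers.  Run on a dataset subset to divergence
# for mel and ana; the polymorphism catch-all parameter is uninformative
# there (all-zero pool) and is excluded from LRT degrees of freedom.
name: divergence-compartment
models:
  cp_base:
    - {param: div.pi, context: divergence, gene_class: piRNA}
    - {param: mel.div.o, species: mel, context: divergence}
    - {param: ana.div.o, species: ana, context: divergence}
    - {param: poly}
  cp_species:
    - {param: mel.div.pi, species: mel, context: divergence, gene_class: piRNA}
    - {param: ana.div.pi, species: ana, context: divergence, gene_class: piRNA}
    - {param: mel.div.o, species: mel, context: divergence}
    - {param: ana.div.o, species: ana, context: divergence}
    - {param: poly}
  cp_comp:
    - {param: div.pi.nuc, context: divergence, gene_class: piRNA, compartment: nuclear}
    - {param: div.pi.cyt, context: divergence, gene_class: piRNA}
    - {param: mel.div.o, species: mel, context: divergence}
    - {param: ana.div.o, species: ana, context: divergence}
    - {param: poly}
  cp_melcomp:
    - {param: mel.div.pi.nuc, species: mel, context: divergence, gene_class: piRNA, compartment: nuclear}
    - {param: mel.div.pi.cyt, species: mel, context: divergence, gene_class: piRNA}
    - {param: ana.div.pi, species: ana, context: divergence, gene_class: piRNA}
    - {param: mel.div.o, species: mel, context: divergence}
    - {param: ana.div.o, species: ana, context: divergence}
    - {param: poly}
  cp_anacomp:
    - {param: ana.div.pi.nuc, species: ana, context: divergence, gene_class: piRNA, compartment: nuclear}
    - {param: ana.div.pi.cyt, species: ana, context: divergence, gene_class: piRNA}
    - {param: mel.div.pi, species: mel, context: divergence, gene_class: piRNA}
    - {param: mel.div.o, species: mel, context: divergence}
    - {param: ana.div.o, species: ana, context: divergence}
    - {param: poly}
  cp_full:
    - {param: mel.div.pi.nuc, species: mel, context: divergence, gene_class: piRNA, compartment: nuclear}
    - {param: mel.div.pi.cyt, species: mel, context: divergence, gene_class: piRNA}
    - {param: ana.div.pi.nuc, species: ana, context: divergence, gene_class: piRNA, compartment: nuclear}
    - {param: ana.div.pi.cyt, species: ana, context: divergence, gene_class: piRNA}
    - {param: mel.div.o, species: mel, context: divergence}
    - {param: ana.div.o, species: ana, context: divergence}
    - {param: poly}
tiers:
  - [cp_base]
  - [cp_species, cp_comp]
  - [cp_melcomp, cp_anacomp]
  - [cp_full]
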