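# Study system catalog: eight sequence classes with a variable central
# base pair X (chain A) / Y (chain B).  Sequences are 5'->3'; the chain B
# sequence carries the Y placeholder at its central position.  P-values are
# opaque hotspot/coldspot annotations carried along for reporting only.
classes:
  I:
    chain_a: GGTTAAXTTAACC
    chain_b: GGTTAAYTTAACC
    palindromic: true
    central_context: AAXTT
    comment: palindromic 13-nt reference class
  II:
    chain_a: GAACCGCXCGCTAGG
    chain_b: CCTAGCGYGCGGTTC
    palindromic: false
    central_context: GCXCG
    comment: derived from a repair-complex crystal-structure duplex
    systems: ["aA:aT", "aG:aC", "aG/aT"]
  III:
    chain_a: GAACCAAXTTCTAGG
    chain_b: CCTAGAAYTTGGTTC
    palindromic: false
    central_context: AAXTT
    comment: class II backbone with the class I central 5-nt segment
    systems: ["aA:aT", "aG:aC", "aG/aT"]
  C1:
    chain_a: GAACCAAXAACTAGG
    chain_b: CCTAGTTYTTGGTTC
    palindromic: false
    central_context: AAXAA
    comment: coldspot context
    p_value: 1.3e-6
    systems: ["aA:aT", "aG:aC", "aG/aT"]
  C2:
    chain_a: GAACCCAXTGCTAGG
    chain_b: CCTAGCAYTGGGTTC
    palindromic: false
    central_context: CAXTG
    comment: coldspot context
    p_value: 9.2e-5
    systems: ["aA:aT", "aG:aC", "aG/aT"]
  H1:
    chain_a: GAACCAGXTACTAGG
    chain_b: CCTAGTAYCTGGTTC
    palindromic: false
    central_context: AGXTA
    comment: hotspot context
    p_value: 1.3e-11
    systems: ["aA:aT", "aG:aC", "aG/aT"]
  H2:
    chain_a: GAACCTCXCACTAGG
    chain_b: CCTAGTGYGAGGTTC
    palindromic: false
    central_context: TCXCA
    comment: hotspot context
    p_value: 2.7e-8
    systems: ["aA:aT", "aG:aC", "aG/aT"]
  H3:
    chain_a: GAACCTGXAACTAGG
    chain_b: CCTAGTTYCAGGTTC
    palindromic: false
    central_context: TGXAA
    comment: hotspot context
    p_value: 6.6e-4
    systems: ["aA:aT", "aG:aC", "aG/aT"]

# class I membership as published, for the string-level enumeration check
class_I_systems:
  anti_anti: ["aA/aA", "aA/aC", "aA/aG", "aA:aT", "aC/aC", "aC/aT",
              "aG:aC", "aG/aG", "aG/aT", "aT/aT"]
  anti_syn: ["aA/sA", "aA/sC", "aA/sG", "aA/sT", "aC/sC", "aC/sT",
             "aG/sC", "aG/sG", "aG/sT", "aT/sT"]
  syn_anti: ["sA/aC", "sA/aG", "sA/aT", "sC/aT", "sG/aC", "sG/aT"]
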