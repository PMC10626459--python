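# IOL-constant registry: one entry per lens model.
# Each entry needs model_name and either an optimized Haigis triple
# (a0, a1, a2) or a manufacturer a_constant; when only the A-constant is
# given, a default triple (a1=0.4, a2=0.1, converted a0) is synthesized
# and marked as such. The A-constants below are nominal manufacturer
# values for the six lens models supported out of the box; replace them
# with optimized triples when available.
- model_name: Rayner
  a_constant: 118.0
- model_name: Akreos Adapt
  a_constant: 118.0
- model_name: 868UV
  a_constant: 118.0
- model_name: Aspira-aA
  a_constant: 118.3
- model_name: Aaren pal
  a_constant: 118.4
- model_name: Tecnis PCB00
  a_constant: 119.3
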