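# regime diagram: relatedness x benefit at a high generation ratio,
# with evolvable host control
variant: control
axes:
  R: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
  benefit_xy: [1.0, 1.3, 1.6, 1.9, 2.2, 2.5, 2.8, 3.1, 3.4, 3.7, 4.0]
fixed:
  generation_ratio: 100
  n_host_generations: 150
margin: 0.2
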