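# Freedson uniaxial cut-points (counts/min) for intensity classification.
# sedentary: [0, light_low); light: [light_low, moderate_low);
# moderate: [moderate_low, vigorous_low); vigorous: [vigorous_low, inf)
light_low: 100
moderate_low: 1952
vigorous_low: 5725
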