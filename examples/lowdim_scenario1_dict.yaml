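# Six-component Gaussian dictionary of the first low-dimensional mixture
# scenario (true weights 0.3/0.3/0.4 at components 1/4/6)
family: gaussian
means: [0.0, 10.0, 20.0, 30.0, 40.0, 50.0]
sigmas: [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
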