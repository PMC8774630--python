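# Seven-component Gaussian dictionary of the second low-dimensional
# mixture scenario (n = 50, true weights 0.1/0.8/0.1 at components 1/4/7)
family: gaussian
means: [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
sigmas: [0.3, 0.2, 0.2, 0.1, 0.2, 0.2, 0.3]
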