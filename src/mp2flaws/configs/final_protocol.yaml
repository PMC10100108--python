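# Suggested combined UNI+FLAWS protocol, 0.65 mm isotropic at 7T.
# 256 slices x 6/8 slice partial Fourier -> 192 excitations, center line 64.
tr_mp2rage: 4000.0
tr_gre: 7.9
ti1: 650.0
ti2: 2280.0
alpha1: 4.0
alpha2: 5.0
n_inner: 256
partial_fourier: 0.75
te: 3.15
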