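# Initial 0.65 mm protocol at TR_MP2RAGE = 5000 ms (TI 650/2220 ms).
# 240 partition steps x 6/8 partial Fourier -> 180 excitations, center line 60.
tr_mp2rage: 5000.0
tr_gre: 7.26
ti1: 650.0
ti2: 2220.0
alpha1: 5.0
alpha2: 7.0
n_inner: 240
partial_fourier: 0.75
te: 3.15
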