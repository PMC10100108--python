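# Adult 7T tissue parameters: T1/T2 in ms, PD relative, D in mm^2/s
WM:  {T1: 1220.0, T2: 45.9, PD: 0.69, D: 0.00070}
GM:  {T1: 2132.0, T2: 55.0, PD: 0.82, D: 0.00080}
CSF: {T1: 3350.0, T2: 1000.0, PD: 1.00, D: 0.00300}
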