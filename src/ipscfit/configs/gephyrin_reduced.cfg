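//FITTING PARAMETERS AND INITIAL VALUES
5
0 syn[0].c1 1.0
1 syn[0].alphab 1.0
2 syn[0].taur 0.2
3 syn[0].taud 8.0
4 nstim.start 20.0
//CONSTRAINTS
0.001 1000
0.35 2
0.05 0.5
3 20
0 100
//DEPENDENCY RULES FOR PARAMETERS NOT FITTED
0
//EXCLUSION RULES
0
//PARAMETERS WARNING (ALL EXCEPT)
1
nstim.start
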