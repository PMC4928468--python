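//FITTING PARAMETERS AND INITIAL VALUES
12
0 syn[0].w 1.0
1 syn[0].taur 0.2
2 syn[0].taud 8.0
3 syn[0].beta 1.0
4 syn[0].alphaf 1.0
5 syn[0].alphab 1.0
6 syn[0].geph 1.0
7 syn[0].phi 1.0
8 syn[0].h 1.0
9 syn[0].h1 1.0
10 syn[0].c1 1.0
11 nstim.start 20.0
//CONSTRAINTS
0.01 100
0.05 0.5
3 20
0.1 10
0.1 10
0.35 2
0.1 10
0.1 1.9
0.1 10
0.1 10
0.001 1000
0 100
//DEPENDENCY RULES FOR PARAMETERS NOT FITTED
1
syn[0].nhalf = syn[0].geph/2
//EXCLUSION RULES
//example: syn[0].geph < syn[0].nhalf^*^syn[0].phi
1
syn[0].geph < syn[0].nhalf^*^syn[0].phi
//PARAMETERS WARNING (ALL EXCEPT)
1
nstim.start
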