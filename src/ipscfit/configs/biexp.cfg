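//FITTING PARAMETERS AND INITIAL VALUES
4
0 syn[0].tau1 1.6
1 syn[0].tau2 7.7
2 nstim.start 0.2
3 nc[0].weight 1.2e-3
//CONSTRAINTS
0 2
2 10
1e-5 1e5
1e-5 1e5
//DEPENDENCY RULES FOR PARAMETERS NOT FITTED
0
//EXCLUSION RULES
//example: (parmlist.o(9).val < syn[0].nhalf^*^parmlist.o(7).val)
//means: syn[0].geph < syn[0].nhalf^*^syn[0].phi
0
//PARAMETERS WARNING (ALL EXCEPT)
0
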