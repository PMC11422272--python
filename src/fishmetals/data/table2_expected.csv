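risk_index,scenario,stratum,display,note
THQ_Cd,FIR1,men,< 0.01,
THQ_Cd,FIR1,women,< 0.01,
THQ_Cd,FIR1,teenagers,< 0.01,
THQ_Cd,FIR1,children,< 0.01,
THQ_Cd,FIR2,men,< 0.01,
THQ_Cd,FIR2,women,< 0.01,
THQ_Cd,FIR2,teenagers,< 0.01,
THQ_Cd,FIR2,children,0.01,
THQ_Pb,FIR1,men,0.29,
THQ_Pb,FIR1,women,0.33,
THQ_Pb,FIR1,teenagers,0.43,
THQ_Pb,FIR1,children,1.08,flagged
THQ_Pb,FIR2,men,1.67,flagged
THQ_Pb,FIR2,women,1.93,flagged
THQ_Pb,FIR2,teenagers,2.51,flagged
THQ_Pb,FIR2,children,6.27,flagged
THQ_Zn,FIR1,men,< 0.01,
THQ_Zn,FIR1,women,< 0.01,
THQ_Zn,FIR1,teenagers,< 0.01,
THQ_Zn,FIR1,children,0.01,
THQ_Zn,FIR2,men,0.01,
THQ_Zn,FIR2,women,0.01,
THQ_Zn,FIR2,teenagers,0.01,
THQ_Zn,FIR2,children,0.03,
HI,FIR1,men,0.29,
HI,FIR1,women,0.33,
HI,FIR1,teenagers,0.44,
HI,FIR1,children,1.09,flagged
HI,FIR2,men,1.68,flagged
HI,FIR2,women,1.94,flagged
HI,FIR2,teenagers,2.53,flagged
HI,FIR2,children,6.31,flagged
CR_Cd,FIR1,men,5.0e-7,
CR_Cd,FIR1,women,5.7e-7,
CR_Cd,FIR1,teenagers,7.5e-7,
CR_Cd,FIR1,children,2.9e-6,erratum: main text gives 1.9e-6 which is the arithmetically consistent value
CR_Cd,FIR2,men,3.3e-6,row prints 7 values for 8 cells; stratum assignment uncertain
CR_Cd,FIR2,women,4.3e-6,row prints 7 values for 8 cells; stratum assignment uncertain
CR_Cd,FIR2,teenagers,1.1e-6,row prints 7 values for 8 cells; stratum assignment uncertain
CR_Cd,FIR2,children,,cell absent in print
CR_Pb,FIR1,men,2.4e-8,
CR_Pb,FIR1,women,2.8e-8,
CR_Pb,FIR1,teenagers,3.7e-8,
CR_Pb,FIR1,children,9.2e-8,
CR_Pb,FIR2,men,1.4e-7,
CR_Pb,FIR2,women,1.6e-7,
CR_Pb,FIR2,teenagers,2.1e-7,
CR_Pb,FIR2,children,5.3e-7,
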