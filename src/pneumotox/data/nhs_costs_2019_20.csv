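resource,weight_expr,unit_cost,code
Initial respiratory appointment (CL),0.417,198.52,WF01B
FU respiratory appointment (CL),0.417,209.12,WF02A
Bronchoscopy,0.237,703.86,DZ69A (OPROC)
PFT,0.417,156.75,DZ52Z (OPROC)
CT Thorax scan,1,68.92,"RD21A (IMAG, outpatient)"
MDT discussion,1,127.45,"Average of CMDT-B, -C, -LG, -OTH, -SPU, -SPG"
FU Oncology appointment (CL),2,200.38,WF01A
Hospital admission (nights),10.5*0.39,473.97,DZ19M (NES)
CCU admission (nights),6.5*0.07,933.51,"CCU03, XC06Z (CC)"
Other immunosuppressive agent,0.043,13195,BNF
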