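subgroup,delta_cost,delta_qalys
Age group: <65 years,1200,0.08
Age group: >=65 years,1800,0.12
Disease severity: Mild,800,0.10
Disease severity: Severe,2400,0.09
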