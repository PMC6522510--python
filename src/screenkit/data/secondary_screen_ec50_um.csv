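compound,MOLM-13,MV4-11,CHRF288-11,CMK,CMS,M07e,ML2,U937
Clofarabine,0.05,0.15,0.37,0.005,0.02,0.01,0.13,0.09
Gemcitabine,0.003,0.002,0.003,0.01,0.03,0.06,0.002,0.01
Gambogic acid,0.19,0.17,0.22,0.36,0.26,0.24,0.15,0.19
Dactinomycin,0.03,0.04,0.001,0.001,0.04,0.001,0.001,0.001
Mitoxantrone,0.01,0.001,0.02,0.04,0.08,0.03,0.24,0.03
Trichostatin A,0.08,0.04,0.04,0.05,0.04,0.09,0.11,0.04
Quisinostat,0.01,0.01,0.01,0.02,0.001,0.004,0.004,0.01
CUDC-907,0.0004,0.0002,0.001,0.002,0.001,0.001,0.002,0.004
Panobinostat,0.18,0.13,0.01,0.003,0.03,0.005,0.01,0.01
Romidepsin,0.001,0.001,0.01,0.01,0.001,0.002,0.004,0.003
NVP-BGT226,0.11,0.05,0.05,0.06,0.01,0.25,0.23,0.08
Cabazitaxel,0.001,0.0003,0.001,0.001,0.001,0.001,0.001,0.001
Ouabain,0.03,0.04,0.04,0.18,0.05,0.06,0.03,0.04
Bortezomib,0.002,0.002,0.002,0.01,0.001,0.001,0.001,0.02
Oprozomib,0.01,0.01,0.03,0.01,0.001,0.01,0.01,0.01
ONX-0914,0.07,0.05,0.17,0.23,0.11,0.08,0.04,0.13
Carfilzomib,0.01,0.001,0.02,0.01,0.001,0.001,0.003,0.01
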