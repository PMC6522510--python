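compound,mechanism_code,fda_approved,pediatric_dose_or_phase1,used_or_investigated_in_aml
Clofarabine,a,true,true,true
Gemcitabine,a,true,true,false
Gambogic acid,c,,,
Dactinomycin,d,true,true,
Mitoxantrone,c,true,,true
Trichostatin A,e,false,,
Quisinostat,e,,,
CUDC-907,e;k,,,
Panobinostat,e,true,,true
Romidepsin,e,true,,
NVP-BGT226,k,false,,
Cabazitaxel,m,true,true,false
Ouabain,o,,,
Bortezomib,p,true,,true
Oprozomib,p,,,
ONX-0914,p,,,
Carfilzomib,p,true,,true
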