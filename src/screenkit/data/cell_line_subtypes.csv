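cell_line,subtype
MOLM-13,MLLr+FLT3-ITD
MV4-11,MLLr+FLT3-ITD
CHRF288-11,AMKL
CMK,AMKL
CMS,AMKL
M07e,AMKL
ML2,MLLr
U937,PICALM/MLLT10
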