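target_id,target_class,difficulty,length_nt
R1107,natural,medium,69
R1108,natural,medium,69
R1116,natural,difficult,157
R1117,natural,easy,30
R1126,synthetic,synthetic,363
R1128,synthetic,synthetic,238
R1136,synthetic,synthetic,374
R1138,synthetic,synthetic,720
R1149,natural,difficult,124
R1156,natural,difficult,135
R1189,natural,difficult,118
R1190,natural,difficult,118
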