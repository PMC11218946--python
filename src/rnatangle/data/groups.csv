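group_id,group_name,method_class,participant_class
TS054,UltraFold,ML,human
TS110,DF_RNA,ML,human
TS227,GinobiFold,traditional,human
TS416,AIchemy_RNA,ML,human
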