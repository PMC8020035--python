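subject,sci_type,asia,lesion,comorbidities,age,scim_pre,scim_post
SCI_01,Incomplete,D,Central Cord,,80,84,89
SCI_02,Complete,A,T7,,29,70,70
SCI_05,Incomplete,D,C4,,38,72,92
SCI_06,Complete,A,T6,,50,49,66
SCI_08,Incomplete,D,C6-C7,,59,100,100
SCI_11,Incomplete,B,C2-C4,"UTI, C2-C3 spinal artery infarct",73,77,100
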