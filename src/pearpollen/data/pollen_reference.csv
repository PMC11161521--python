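variety,stage,per_flower_mg,effective_mg
Chojuro,Early,0.367,0.201
Chojuro,Best,0.757,0.386
Chojuro,Late,0.387,0.257
Chojuro,Too late,0,0
Shinko,Early,0.960,0.671
Shinko,Best,1.347,0.871
Shinko,Late,0.720,0.545
Shinko,Too late,0,0
Nepal,Early,0.902,0.428
Nepal,Best,1.137,0.795
Nepal,Late,1.141,0.783
Nepal,Too late,0,0
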