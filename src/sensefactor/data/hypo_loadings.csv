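item,specific_factor,lambda_g,lambda_s
SEQ2 Q3/SEQ3 Q8,Speech,0.446,0.725
SP1 Q6/SP2 Q6,Speech,0.344,0.726
SP1 Q7/SP2 Q7,Speech,0.416,0.848
SEQ2 Q19/SEQ3 Q53,PainTemp,0.413,0.690
SP1 Q42/SP2 Q23/SP2 Q24,PainTemp,0.441,0.870
SEQ3 Q56,PainTemp,0.447,0.478
SEQ2 Q10/SEQ3 Q22/SEQ3 Q23 [Visual],,0.541,
SP1 Q46/SP2 Q26 [Tactile],,0.470,
SEQ2 Q4/SEQ3 Q4 [Auditory],,0.554,
SEQ3 Q69 [Olfactory],,0.445,
SEQ3 Q74 [Gustatory],,0.448,
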