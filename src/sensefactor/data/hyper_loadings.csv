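item,specific_factor,lambda_g,lambda_s
SP1 Q1/SP2 Q1,Auditory,0.513,0.699
SP1 Q2/SP2 Q2,Auditory,0.469,0.683
SEQ2 Q1/SEQ3 Q1,Auditory,0.469,0.753
SEQ3 Q9,Auditory,0.611,0.475
SEQ2 Q8/SEQ3 Q15,Visual,0.571,0.594
SP1 Q10/SP2 Q15,Visual,0.563,0.677
SP1 Q14/SP2 Q13,Visual,0.649,0.601
SP1 Q15,Visual,0.565,0.599
SP1 Q30/SP2 Q16/SEQ2 Q15/SEQ3 Q49,Tactile,0.449,0.449
SP1 Q36/SP2 Q18,Tactile,0.608,0.261
SEQ2 Q16/SEQ3 Q38,Tactile,0.564,0.100
SP1 Q33,Tactile,0.650,0.324
SEQ2 Q22/SEQ3 Q59,Gustatory,0.451,0.695
SP1 Q55/SP2 Q44,Gustatory,0.465,0.786
SP1 Q56/SP2 Q45,Gustatory,0.454,0.721
SEQ3 Q70,Gustatory,0.482,0.393
SEQ3 Q61,Olfactory,0.619,0.685
SEQ3 Q66,Olfactory,0.543,0.713
SEQ3 Q73,Olfactory,0.547,0.413
SP1 Q18,Movement,0.482,0.701
SP1 Q19,Movement,0.462,0.680
SP1 Q20,Movement,0.408,0.637
SEQ3 Q83,Movement,0.464,0.621
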