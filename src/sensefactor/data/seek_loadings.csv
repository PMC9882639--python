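item,specific_factor,lambda_g,lambda_s
SEQ2 Q9/SEQ3 Q17,Visual,0.691,0.409
SP1 Q97/SP2 Q80/SP2 Q81,Visual,0.593,0.296
SEQ3 Q19,Visual,0.656,0.310
SEQ3 Q27,Visual,0.552,0.558
SEQ3 Q29,Visual,0.526,0.487
SEQ3 Q30,Visual,0.572,0.486
SP1 Q45/SP2 Q21/SP2 Q25,Tactile,0.598,0.364
SEQ2 Q36f/SEQ3 Q45,Tactile,0.551,0.688
SEQ3 Q37,Tactile,0.436,0.413
SEQ3 Q50,Tactile,0.672,0.131
SEQ2 Q25/SEQ3 Q62,OralTactile,0.441,0.796
SP1 Q64,OralTactile,0.433,0.856
SP1 Q65,OralTactile,0.421,0.772
SEQ3 Q71,OralTactile,0.525,0.706
SP1 Q24/SP1 Q25/SP2 Q27,Movement,0.611,0.483
SEQ2 Q27/SEQ3 Q76,Movement,0.624,0.358
SP1 Q84/SP2 Q60,Movement,0.599,0.160
SP1 Q26,Movement,0.683,0.651
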