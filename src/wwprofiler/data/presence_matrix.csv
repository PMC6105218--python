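compound,hall_of_separators:A,hall_of_separators:B,hall_of_separators:C,secondary_settlement:A,secondary_settlement:B,secondary_settlement:C,effluent:A,effluent:B,effluent:C
Acesulfame-K,+,+,+,-,+,+,-,+,+
Aspartame,-,-,+,-,-,-,-,-,-
Butyl paraben,-,-,-,-,-,-,-,-,-
Caffeine,+,+,+,-,-,-,-,-,-
Carbamazepine,+,+,+,+,+,+,+,+,+
Cyclamate,+,+,+,-,-,+,-,-,-
Ethyl paraben,+,-,-,-,-,-,-,-,-
Ibuprofen,-,-,+,-,-,-,-,-,-
Methyl paraben,+,-,-,-,-,-,-,-,-
Paracetamol,+,+,+,-,-,-,-,-,-
Saccharin,+,+,+,-,+,+,-,-,-
Sucralose,-,-,+,-,-,+,-,-,+
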