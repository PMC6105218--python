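name	formula	polarity	rt_min	precursor_mz	product_mz	collision_energy_v	mz_convention
Acesulfame-K	C4H5NO4S	negative	5.5	161.9861	82.03	16.5	hydrogen
Aspartame	C14H18N2O5	negative	19.7	293.1137	261.08	21.7	hydrogen
Butyl paraben	C11H14O3	negative	19.3	193.0870	92.03	17.7	proton
Caffeine	C8H10N4O2	positive	11.2	195.0876	138.06	17.8	proton
Carbamazepine	C15H12N2O	positive	16.9	237.1022	194.10	19.5	proton
Cyclamate	C6H13NO3S	negative	8.7	178.0538	79.95	17.1	hydrogen
Ethyl paraben	C9H10O3	negative	16.5	165.0557	92.03	16.5	proton
Ibuprofen	C13H18O2	negative	20.9	205.1229	160.88	18.2	hydrogen
Methyl paraben	C8H8O3	negative	14.8	151.0401	92.03	16.0	proton
Paracetamol	C8H9NO2	positive	8.7	152.0706	110.06	16.1	proton
Saccharin	C7H5NO3S	negative	7.5	181.9912	105.96	17.3	hydrogen
Sucralose	C12H19Cl3O8	negative	11.8	395.0067	359.00	15.0	hydrogen
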