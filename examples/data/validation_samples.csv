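shed_id,date,t,d18O_W,d2H_W,d18O_M,d2H_M,temp_2wk,outdoor_summer
Torrile,20/01/2019,20,-8.78,,-8.16,,,
Torrile,25/02/2019,56,-8.86,,-7.55,,,
Villa Minozzo,05/02/2019,36,-9.10,,-7.81,,,
Quattro Castella,05/02/2019,36,-8.77,,-7.92,,,
Viarolo,24/12/2018,,-7.51,,-6.75,,,
L1,08/08/2019,220,-9.83,,-6.90,,,
L2,01/03/2019,150,-8.83,,-7.26,,,
L3,01/07/2019,182,-8.15,,-6.73,,,
L4,02/02/2021,30,-9.32,,-7.20,,,
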