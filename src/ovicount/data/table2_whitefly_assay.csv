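species,accession,plant,cage,alive,dead,eggs_vhx7000,eggs_autoento
S. habrochaites,LA1777,1,1,0,5,0,0
S. habrochaites,LA1777,1,2,0,5,0,0
S. habrochaites,LA1777,2,1,1,4,34,37
S. habrochaites,LA1777,2,2,0,5,14,0
S. habrochaites,LA1777,3,1,0,5,38,38
S. habrochaites,LA1777,3,2,1,4,0,0
S. lycopersicum,Moneymaker,1,1,5,0,128,171
S. lycopersicum,Moneymaker,1,2,5,0,102,77
S. lycopersicum,Moneymaker,2,1,3,0,119,91
S. lycopersicum,Moneymaker,2,2,5,0,195,149
S. lycopersicum,Moneymaker,3,1,4,0,220,59
S. lycopersicum,Moneymaker,3,2,5,0,220,227
S. tuberosum,RH89-039-16,1,1,3,1,134,113
S. tuberosum,RH89-039-16,1,2,5,0,210,194
S. tuberosum,RH89-039-16,2,1,3,1,140,119
S. tuberosum,RH89-039-16,2,2,4,1,207,194
S. tuberosum,RH89-039-16,3,1,5,0,157,108
S. tuberosum,RH89-039-16,3,2,4,0,58,43
S. berthaultii,BER481-3,1,1,0,5,52,33
S. berthaultii,BER481-3,1,2,0,5,0,0
S. berthaultii,BER481-3,2,1,0,5,0,0
S. berthaultii,BER481-3,2,2,0,5,0,0
S. berthaultii,BER481-3,3,1,0,5,0,0
S. berthaultii,BER481-3,3,2,2,2,0,0
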