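name,n_C,n_H,n_O,n_N,phase_hint,synonyms
acetate,2,4,2,0,liquid,C2;acetic acid;HAc
propionate,3,6,2,0,liquid,C3;propionic acid
n-butyrate,4,8,2,0,liquid,C4;n-C4;butyrate;butyric acid
i-butyrate,4,8,2,0,liquid,iC4;i-C4;isobutyrate
n-valerate,5,10,2,0,liquid,C5;n-C5;valerate
i-valerate,5,10,2,0,liquid,iC5;i-C5;isovalerate
n-caproate,6,12,2,0,liquid,C6;n-C6;caproate;hexanoate
i-caproate,6,12,2,0,liquid,iC6;i-C6;isocaproate
n-heptanoate,7,14,2,0,liquid,C7;n-C7;heptanoate;enanthate
n-caprylate,8,16,2,0,liquid,C8;n-C8;caprylate;octanoate
ethanol,2,6,1,0,liquid,EtOH
n-propanol,3,8,1,0,liquid,PrOH;1-propanol;propanol
n-butanol,4,10,1,0,liquid,BuOH;1-butanol;butanol
n-pentanol,5,12,1,0,liquid,PeOH;1-pentanol;pentanol
n-hexanol,6,14,1,0,liquid,HexOH;1-hexanol;hexanol
CO2,1,0,2,0,both,carbon dioxide
CH4,1,4,0,0,gas,methane
H2,0,2,0,0,gas,hydrogen
N2,0,0,0,2,gas,nitrogen
O2,0,0,2,0,gas,oxygen
H2O,0,2,1,0,liquid,water
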