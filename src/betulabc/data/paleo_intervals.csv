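name,start_ka,end_ka,region,source
MIS 16 NW Eurasian ice expansion,676,621,Eurasia,Batchelor et al. 2019
Laurentide-Cordilleran corridor closed,677,429,North America,Batchelor et al. 2019
MIS 6,190,132,global,Lisiecki & Raymo 2005; Batchelor et al. 2019
MIS 4 reduced N American ice / corridor open,117,60,North America,Batchelor et al. 2019; Dalton et al. 2022
MIS 3 corridor reopening,55,30,North America,Batchelor et al. 2019; Dalton et al. 2022
Bering Land Bridge emergence,35.7,11,Beringia,Farmer et al. 2023
Eurasian ice sheet post-LGM retreat,23,21,Eurasia,Hughes et al. 2016
Svalbard first occurrence ~7.5 ka (sedaDNA),8.0,7.0,Svalbard,Alsos et al. 2016
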