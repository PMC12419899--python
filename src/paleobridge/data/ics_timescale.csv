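name,level,age_older,age_younger
Quaternary,period,2.58,0.0
Neogene,period,23.03,2.58
Paleogene,period,66.0,23.03
Cretaceous,period,145.0,66.0
Jurassic,period,201.4,145.0
Triassic,period,251.902,201.4
Permian,period,298.9,251.902
Carboniferous,period,358.9,298.9
Devonian,period,419.2,358.9
Holocene,stage,0.0117,0.0
Upper Pleistocene,stage,0.129,0.0117
Chibanian,stage,0.774,0.129
Calabrian,stage,1.80,0.774
Gelasian,stage,2.58,1.80
Piacenzian,stage,3.600,2.58
Zanclean,stage,5.333,3.600
Messinian,stage,7.246,5.333
Tortonian,stage,11.63,7.246
Serravallian,stage,13.82,11.63
Langhian,stage,15.98,13.82
Burdigalian,stage,20.44,15.98
Aquitanian,stage,23.03,20.44
Chattian,stage,27.82,23.03
Rupelian,stage,33.9,27.82
Priabonian,stage,37.71,33.9
Bartonian,stage,41.2,37.71
Lutetian,stage,47.8,41.2
Ypresian,stage,56.0,47.8
Thanetian,stage,59.2,56.0
Selandian,stage,61.6,59.2
Danian,stage,66.0,61.6
Maastrichtian,stage,72.1,66.0
Campanian,stage,83.6,72.1
Santonian,stage,86.3,83.6
Coniacian,stage,89.8,86.3
Turonian,stage,93.9,89.8
Cenomanian,stage,100.5,93.9
Albian,stage,113.0,100.5
Aptian,stage,121.4,113.0
Barremian,stage,125.77,121.4
Hauterivian,stage,132.6,125.77
Valanginian,stage,139.8,132.6
Berriasian,stage,145.0,139.8
Tithonian,stage,149.2,145.0
Kimmeridgian,stage,154.8,149.2
Oxfordian,stage,161.5,154.8
Callovian,stage,165.3,161.5
Bathonian,stage,168.2,165.3
Bajocian,stage,170.9,168.2
Aalenian,stage,174.7,170.9
Toarcian,stage,184.2,174.7
Pliensbachian,stage,192.9,184.2
Sinemurian,stage,199.5,192.9
Hettangian,stage,201.4,199.5
Rhaetian,stage,208.5,201.4
Norian,stage,227.0,208.5
Carnian,stage,237.0,227.0
Ladinian,stage,242.0,237.0
Anisian,stage,247.2,242.0
Olenekian,stage,251.2,247.2
Induan,stage,251.902,251.2
Changhsingian,stage,254.14,251.902
Wuchiapingian,stage,259.51,254.14
Capitanian,stage,264.28,259.51
Wordian,stage,266.9,264.28
Roadian,stage,273.01,266.9
Kungurian,stage,283.5,273.01
Artinskian,stage,290.1,283.5
Sakmarian,stage,293.52,290.1
Asselian,stage,298.9,293.52
Gzhelian,stage,303.7,298.9
Kasimovian,stage,307.0,303.7
Moscovian,stage,315.2,307.0
Bashkirian,stage,323.2,315.2
Serpukhovian,stage,330.9,323.2
Visean,stage,346.7,330.9
Tournaisian,stage,358.9,346.7
Famennian,stage,372.2,358.9
Frasnian,stage,382.7,372.2
Givetian,stage,387.7,382.7
Eifelian,stage,393.3,387.7
Emsian,stage,407.6,393.3
Pragian,stage,410.8,407.6
Lochkovian,stage,419.2,410.8
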