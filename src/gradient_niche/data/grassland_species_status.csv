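species,redlist,regions,occurrence,abundance,LUI,grazing,mowing,fertilization,pH,moisture
Abida secale,G,A,1,1,neutral,neutral,neutral,neutral,neutral,neutral
Acanthinula aculeata,*,AH,2,2,neutral,neutral,neutral,neutral,neutral,neutral
Aegopinella nitens,*,AHS,9,15,loser,neutral,neutral,neutral,neutral,neutral
Aegopinella nitidula,*,H,1,2,neutral,neutral,winner,neutral,neutral,neutral
Aegopinella pura,*,AH,21,38,neutral,neutral,neutral,neutral,neutral,neutral
Candidula unifasciata,2,AH,9,46,neutral,neutral,neutral,neutral,high,low
Carychium minimum,*,AS,23,381,neutral,neutral,neutral,loser,high,high
Carychium tridentatum,*,AHS,30,142,neutral,neutral,neutral,neutral,high,high
Cecilioides acicula,*,AH,2,2,neutral,winner,neutral,neutral,neutral,neutral
Cepaea hortensis,*,AH,3,3,neutral,winner,loser,neutral,neutral,neutral
Cochlicopa lubrica,*,AHS,77,546,neutral,neutral,neutral,neutral,neutral,neutral
Cochlodina laminata,*,H,1,1,neutral,neutral,neutral,neutral,neutral,neutral
Columella aspera,*,A,1,1,neutral,neutral,neutral,neutral,neutral,neutral
Discus rotundatus,*,AHS,12,28,neutral,neutral,neutral,winner,neutral,low
Eucobresia diaphana,*,H,1,1,neutral,neutral,neutral,neutral,neutral,neutral
Euconulus fulvus,*,S,1,1,neutral,neutral,neutral,neutral,neutral,neutral
Euomphalia strigella,G,A,1,1,neutral,neutral,neutral,neutral,neutral,neutral
Granaria frumentum,2,A,2,18,loser,neutral,neutral,neutral,high,neutral
Helicella itala,3,AH,11,28,loser,neutral,neutral,neutral,high,neutral
Helicodonta obvoluta,*,A,1,1,neutral,neutral,neutral,neutral,neutral,neutral
Helix pomatia,*,H,3,6,neutral,neutral,neutral,neutral,mid-specialist,neutral
Macrogastra ventricosa,*,AH,3,3,neutral,neutral,neutral,neutral,neutral,neutral
Monacha cartusiana,*,HS,2,34,winner,neutral,neutral,neutral,neutral,neutral
Monachoides incarnatus,*,AH,3,3,neutral,neutral,neutral,neutral,neutral,neutral
Nesovitrea hammonis,*,AHS,16,35,loser,neutral,neutral,neutral,low,neutral
Oxychilus draparnaudi,*,A,1,2,neutral,neutral,neutral,winner,neutral,neutral
Platyla polita,3,A,1,1,neutral,neutral,neutral,neutral,neutral,neutral
Pseudotrichia rubiginosa,2,S,1,1,neutral,neutral,neutral,neutral,high,neutral
Punctum pygmaeum,*,AHS,14,28,loser,neutral,neutral,neutral,neutral,neutral
Pupilla muscorum,V,AHS,70,1087,neutral,neutral,neutral,neutral,high,neutral
Pupilla alpicola,R,S,12,530,neutral,neutral,neutral,neutral,neutral,neutral
Succinea putris,*,S,13,165,neutral,neutral,neutral,neutral,neutral,neutral
Succinella oblonga,*,AHS,25,57,neutral,neutral,neutral,neutral,neutral,mid-specialist
Trochulus hispidus,*,AHS,29,215,loser,neutral,neutral,neutral,high,neutral
Trochulus sericeus,*,AH,9,14,neutral,neutral,neutral,mid-specialist,neutral,neutral
Trochulus striolatus,V,A,1,1,neutral,neutral,neutral,neutral,neutral,neutral
Truncatellina cylindrica,3,AH,4,14,loser,neutral,neutral,neutral,high,low
Vallonia costata,*,AHS,40,493,neutral,neutral,neutral,neutral,mid-specialist,neutral
Vallonia enniensis,1,AS,5,63,neutral,neutral,neutral,neutral,high,neutral
Vallonia excentrica,*,AHS,106,1829,neutral,neutral,neutral,neutral,neutral,low
Vallonia pulchella,*,AHS,96,3456,neutral,neutral,neutral,neutral,neutral,high
Vertigo angustior,3,S,9,47,neutral,neutral,neutral,neutral,neutral,neutral
Vertigo antivertigo,V,AS,12,102,neutral,neutral,neutral,loser,high,neutral
Vertigo pygmaea,*,AHS,69,355,loser,neutral,neutral,neutral,neutral,high
Vertigo substriata,3,S,1,2,neutral,neutral,neutral,neutral,neutral,neutral
Vitrea contracta,*,AH,5,8,loser,neutral,neutral,neutral,neutral,neutral
Vitrea diaphana,G,H,2,2,neutral,neutral,neutral,neutral,neutral,neutral
Vitrina pellucida,*,AHS,10,16,loser,neutral,neutral,neutral,neutral,mid-specialist
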