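species,redlist,regions,occurrence,abundance,FORMI,Inonat,Idwcut,Iharv,pH,moisture
Acanthinula aculeata,*,AHS,37,61,neutral,neutral,neutral,neutral,neutral,neutral
Aegopinella nitens,*,AHS,62,123,winner,neutral,neutral,neutral,neutral,neutral
Aegopinella nitidula,*,AH,11,15,neutral,neutral,neutral,loser,mid-specialist,mid-specialist
Aegopinella pura,*,AHS,91,422,neutral,neutral,neutral,neutral,high,high
Arianta arbustorum,*,AH,14,24,neutral,neutral,loser,neutral,neutral,neutral
Carychium minimum,*,AH,37,115,winner,neutral,winner,neutral,high,neutral
Carychium tridentatum,*,AHS,74,612,neutral,neutral,neutral,neutral,high,high
Cecilioides acicula,*,AHS,4,4,neutral,neutral,neutral,loser,neutral,low
Cepaea hortensis,*,AH,26,82,loser,loser,loser,loser,low,neutral
Cepaea nemoralis,*,H,15,57,neutral,neutral,neutral,neutral,neutral,neutral
Clausilia bidentata,*,HS,12,14,neutral,neutral,neutral,neutral,neutral,neutral
Cochlicopa lubrica,*,AHS,29,62,winner,neutral,winner,winner,high,neutral
Cochlicopa lubricella,V,A,1,2,neutral,neutral,neutral,neutral,neutral,neutral
Cochlodina laminata,*,AH,19,27,neutral,neutral,neutral,neutral,neutral,neutral
Discus rotundatus,*,AHS,97,362,neutral,neutral,neutral,neutral,neutral,neutral
Ena montana,V,AH,10,12,mid-specialist,neutral,neutral,neutral,high,neutral
Euconulus fulvus,*,AHS,52,86,neutral,neutral,mid-specialist,neutral,low,low
Euomphalia strigella,G,A,1,1,neutral,neutral,neutral,neutral,neutral,neutral
Helicodonta obvoluta,*,AH,27,77,loser,neutral,loser,loser,neutral,neutral
Helix pomatia,*,H,24,87,winner,winner,winner,winner,neutral,neutral
Isognomostoma isognomostomos,*,A,3,3,neutral,neutral,neutral,neutral,neutral,neutral
Macrogastra plicatula,V,A,1,1,neutral,neutral,neutral,winner,neutral,neutral
Macrogastra ventricosa,*,AH,5,6,neutral,neutral,neutral,neutral,neutral,neutral
Monacha cartusiana,*,H,2,2,neutral,neutral,winner,neutral,neutral,neutral
Monachoides incarnatus,*,AH,46,118,neutral,neutral,neutral,neutral,neutral,neutral
Nesovitrea hammonis,*,AHS,59,169,winner,winner,neutral,loser,low,low
Nesovitrea petronella,2,S,1,4,neutral,neutral,neutral,neutral,neutral,neutral
Oxychilus cellarius,*,H,7,12,neutral,neutral,neutral,neutral,neutral,neutral
Oxychilus draparnaudi,*,H,11,15,neutral,neutral,neutral,winner,neutral,neutral
Platyla polita,3,AH,10,23,neutral,loser,neutral,neutral,neutral,neutral
Punctum pygmaeum,*,AHS,50,180,neutral,neutral,neutral,neutral,neutral,low
Pupilla muscorum,V,HS,2,12,neutral,neutral,neutral,neutral,neutral,neutral
Succinella oblonga,*,A,2,2,neutral,neutral,neutral,neutral,neutral,neutral
Trochulus hispidus,*,AH,11,16,neutral,neutral,neutral,neutral,neutral,neutral
Trochulus sericeus,*,AH,8,12,neutral,neutral,neutral,neutral,neutral,neutral
Trochulus striolatus,V,A,16,25,neutral,neutral,neutral,neutral,neutral,low
Urticicola umbrosus,V,S,1,1,neutral,neutral,neutral,neutral,neutral,neutral
Vallonia costata,*,AS,2,3,neutral,neutral,neutral,neutral,neutral,neutral
Vallonia excentrica,*,AH,7,25,neutral,neutral,neutral,loser,neutral,neutral
Vallonia pulchella,*,AHS,14,38,neutral,neutral,neutral,neutral,low,low
Vertigo angustior,3,A,1,1,neutral,winner,neutral,neutral,neutral,neutral
Vertigo pygmaea,*,HS,3,9,neutral,neutral,neutral,neutral,neutral,neutral
Vertigo substriata,3,AS,2,3,neutral,neutral,neutral,neutral,neutral,neutral
Vitrea contracta,*,AHS,40,89,neutral,neutral,neutral,neutral,high,neutral
Vitrea crystallina,*,AH,16,30,neutral,neutral,neutral,mid-specialist,neutral,neutral
Vitrea diaphana,G,H,11,27,neutral,neutral,neutral,neutral,neutral,neutral
Vitrina pellucida,*,S,1,1,winner,neutral,neutral,neutral,neutral,neutral
Vitrinobrachium breve,*,A,2,2,neutral,neutral,neutral,neutral,low,neutral
Zonitoides nitidus,*,AS,2,2,neutral,winner,neutral,neutral,neutral,neutral
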