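name,heavy,light,heavy_cdrs,light_cdrs,cdrh3
Enfortumab,98,98,96,100,100
Racotumomab,97,100,90,100,92
Tabalumab,97,99,96,100,100
Emapalumab,97,99,93,95,87
Tremelimumab,97,97,94,94,88
Ascrinvacumab,96,100,96,100,100
Derlotuximab,96,100,89,100,92
Zolbetuximab,96,100,88,100,81
Ganitumab,96,99,92,100,91
Rilotumumab,96,98,93,94,100
Durvalumab,96,98,90,94,92
Patritumab,96,97,92,95,90
Brazikumab,96,96,90,95,94
Carotuximab,95,100,85,100,77
Varlilumab,95,98,89,100,91
Brodalumab,95,96,88,100,100
Futuximab,95,92,87,88,81
Ramucirumab,95,87,100,88,100
Zanolimumab,94,99,100,100,100
Foravirumab,94,98,89,100,100
Dusigitumab,94,97,100,86,100
Rituximab,94,97,90,94,85
Muromonab,94,97,82,100,83
Ublituximab,94,96,96,88,100
Dectrekumab,94,96,93,95,100
Necitumumab,94,95,93,94,92
Cixutumumab,94,94,89,85,82
Fasinumab,94,93,89,88,83
Sifalimumab,93,100,88,100,100
Modotuximab,93,100,82,100,91
Golimumab,93,99,88,94,94
Brentuximab,93,98,96,100,100
Suvratoxumab,93,98,87,94,87
Zalutumumab,93,98,85,100,88
Bavituximab,93,98,82,94,92
Basiliximab,93,97,88,93,90
Radretumab,93,96,80,84,100
Ofatumumab,92,100,90,100,93
Bezlotoxumab,92,100,89,100,91
Daratumumab,92,100,83,100,86
Inclacumab,92,100,75,100,88
Siltuximab,92,99,89,100,91
Canakinumab,92,99,85,100,100
Lirilumab,92,99,84,100,87
Abrilumab,92,97,85,100,90
Tisotumab,92,97,81,100,81
Indusatumab,92,96,82,100,84
Carlumab,92,92,82,70,83
Tovetumab,92,90,86,89,92
Utomilumab,92,89,88,55,100
Tesidolumab,92,87,92,65,100
Glembatumumab,91,99,92,100,100
Ipilimumab,91,99,88,100,90
Iratumumab,91,98,85,100,100
Cetuximab,91,97,82,94,92
Burosumab,91,97,80,94,90
Anifrolumab,91,96,84,89,90
Pritoxaximab,91,96,80,100,80
Seribantumab,91,95,78,95,83
Girentuximab,91,95,78,88,91
Guselkumab,91,94,80,82,90
Lenzilumab,91,91,78,83,83
Abagovomab,91,90,89,94,100
Domagrozumab,91,89,92,100,88
Briakinumab,91,88,87,65,75
Otelixizumab,91,71,82,75,83
Intetumumab,90,100,85,100,91
Icrucumab,90,100,82,100,78
Foralumab,90,100,81,100,90
Fulranumab,90,100,78,100,93
Aducanumab,90,100,78,100,88
Sarilumab,90,99,88,100,100
Bleselumab,90,98,80,100,84
Tezepelumab,90,98,80,100,80
Opicinumab,90,98,77,100,90
Panitumumab,90,97,89,94,90
Tomuzotuximab,90,97,82,94,92
Timolumab,90,97,80,100,100
Adalimumab,90,97,80,94,71
Figitumumab,90,96,91,100,88
Evolocumab,90,96,91,90,100
Berlimatoxumab,90,95,89,83,90
Tralokinumab,90,95,80,85,80
Ensituximab,90,94,81,94,85
Anetumab,90,92,82,73,84
Setrusumab,90,91,84,78,90
Itolizumab,90,90,82,88,83
Ianalumab,90,88,78,73,71
Elotuzumab,90,87,96,100,100
Emibetuzumab,90,87,87,94,100
Evinacumab,89,100,91,100,94
Eldelumab,89,100,81,100,94
Nivolumab,89,100,77,100,100
Avelumab,89,100,75,100,84
Denosumab,89,98,87,100,80
Atidortoxumab,89,98,67,88,83
Setoxaximab,89,96,85,100,91
Drozitumab,89,96,80,90,85
Indatuximab,89,95,87,94,100
Tarextumab,89,94,75,89,75
Amatuximab,89,93,82,94,100
Infliximab,89,93,75,83,90
Lorvatuzumab,89,92,88,86,100
Bimagrumab,89,92,87,73,100
Solanezumab,89,92,80,91,100
Mavrilimumab,89,91,72,73,61
Camrelizumab,89,90,92,88,100
Tigatuzumab,89,87,89,100,83
Anrukinzumab,89,87,85,90,91
Urelumab,88,100,80,100,86
Secukinumab,88,100,80,100,80
Olaratumab,88,100,77,100,78
Erenumab,88,99,71,100,82
Alirocumab,88,96,85,95,90
Gantenerumab,88,94,68,89,63
Orticumab,88,92,73,77,78
Crenezumab,88,91,95,100,100
Concizumab,88,91,80,95,85
Bapineuzumab,88,91,75,100,83
Actoxumab,87,100,83,100,86
Dupilumab,87,97,76,95,72
Rafivirumab,87,95,75,83,70
Margetuximab,87,94,82,94,84
Trevogrumab,87,94,79,88,69
Dinutuximab,87,90,86,95,83
Mirvetuximab,87,90,77,100,90
Olendalizumab,87,88,75,100,92
Quilizumab,87,86,88,91,100
Obiltoxaximab,87,85,100,100,100
Lampalizumab,87,83,79,94,75
Pamrevlumab,86,100,82,100,92
Fletikumab,86,100,80,100,85
Lanadelumab,86,100,67,100,73
Ustekinumab,86,99,78,100,83
Teprotumumab,86,98,85,100,90
Refanezumab,86,96,80,100,73
Galiximab,86,94,58,90,63
Coltuximab,86,92,96,86,100
Ibalizumab,86,92,87,95,80
Isatuximab,86,91,89,94,92
Otlertuzumab,86,90,92,77,88
Rovalpituzumab,86,90,88,94,90
Landogrozumab,86,89,81,89,100
Daclizumab,86,87,92,88,100
Etaracizumab,86,87,84,88,90
Enokizumab,86,87,80,72,86
Robatumumab,86,87,77,100,91
Tislelizumab,86,86,88,83,91
Lacnotuzumab,86,85,88,94,90
Panobacumab,85,100,84,100,80
Fezakinumab,85,96,70,95,71
Fresolimumab,85,95,62,89,84
Romosozumab,85,93,84,100,81
Dalotuzumab,85,91,80,100,90
Imgatuzumab,85,90,68,76,92
Bococizumab,85,89,77,83,81
Atezolizumab,85,89,77,77,90
Visilizumab,85,88,89,100,100
Lodelcizumab,85,88,70,70,90
Lintuzumab,85,87,96,100,100
Bimekizumab,85,84,67,66,66
Veltuzumab,85,82,90,94,92
Rozanolixizumab,85,82,73,82,80
Codrituzumab,84,91,83,91,87
Plozalizumab,84,91,73,100,87
Simtuzumab,84,90,92,100,100
Mogamulizumab,84,88,67,78,75
Tildrakizumab,84,87,92,100,100
Gevokizumab,84,86,79,88,75
Sacituzumab,84,85,96,94,100
Gedivumab,83,93,67,80,55
Obinutuzumab,83,91,78,100,83
Ozanezumab,83,90,90,100,83
Ixekizumab,83,90,78,91,75
Abituzumab,83,89,85,100,90
Trastuzumab,83,89,82,94,84
Etrolizumab,83,89,76,72,100
Ponezumab,83,89,64,78,77
Matuzumab,83,85,83,88,92
Motavizumab,83,85,75,88,83
Inebilizumab,83,84,90,90,92
Lifastuzumab,83,84,65,78,76
Tanezumab,82,91,80,83,86
Olokizumab,82,90,65,72,81
Ocrelizumab,82,88,93,94,93
Sirukumab,82,88,75,82,83
Andecaliximab,82,85,87,77,100
Palivizumab,82,84,86,94,100
Lumiliximab,81,94,59,83,88
Tocilizumab,81,92,82,100,83
Galcanezumab,81,90,75,83,83
Duligotuzumab,81,90,63,77,78
Roledumab,81,89,68,94,73
Vadastuximab,81,88,88,100,100
Vedolizumab,81,88,86,95,85
Mirikizumab,81,88,83,77,87
Natalizumab,81,87,90,100,100
Eculizumab,81,87,83,100,86
Pinatuzumab,81,86,89,86,100
Ficlatuzumab,81,86,81,88,90
Eptinezumab,81,80,70,29,100
Belimumab,80,98,62,100,62
Crizanlizumab,80,91,90,86,93
Depatuxizumab,80,88,76,94,88
Pertuzumab,80,88,75,83,91
Ligelizumab,80,88,71,88,81
Blosozumab,80,88,66,88,81
Ravulizumab,80,87,77,100,86
Fremanezumab,80,87,67,77,53
Clazakizumab,80,87,65,57,78
Pembrolizumab,80,86,86,90,84
Inotuzumab,80,82,80,95,100
Pidilizumab,80,82,76,94,90
Vatelizumab,80,79,82,88,92
Benralizumab,79,89,83,83,71
Certolizumab,79,87,81,100,100
Lebrikizumab,79,85,74,95,91
Epratuzumab,79,84,84,95,88
Satralizumab,79,84,71,72,83
Risankizumab,79,83,82,83,84
Reslizumab,78,89,92,77,100
Onartuzumab,78,85,78,87,75
Farletuzumab,78,82,96,90,100
Bevacizumab,77,93,90,88,93
Vonlerolizumab,77,92,65,94,80
Idarucizumab,77,91,83,95,87
Polatuzumab,77,90,80,95,80
Rontalizumab,77,88,76,95,90
Parsatuzumab,77,86,81,82,93
Gemtuzumab,77,83,80,86,88
Spartalizumab,77,83,76,91,90
Efalizumab,76,94,83,100,85
Alemtuzumab,76,90,80,66,91
Dacetuzumab,76,84,82,91,85
Tregalizumab,76,84,72,100,93
Omalizumab,75,90,76,100,71
Nimotuzumab,75,81,68,95,62
Pateclizumab,74,91,81,88,81
Teplizumab,74,82,82,100,83
Ranibizumab,73,92,81,88,93
Mepolizumab,72,92,78,95,84
Ontuxizumab,69,85,78,84,82
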