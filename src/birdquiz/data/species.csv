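id,english_name,binomial,abbreviation,song_type,similar_abbrev,similarity_level
1,Brown-eared Bulbul,Hypsipetes amaurotis,Hyam,call,,
2,Japanese Bush Warbler,Cettia diphone,Cedi,song,,
3,Eurasian Tree Sparrow,Passer montanus,Pamo,call,,
4,Large-billed Crow,Corvus macrorhynchos,Coma,call,Coco,E
5,Chinese Hwamei,Garrulax canorus,Gaca,song,Fina,E
6,Common Pheasant,Phasianus colchicus,Phco,call,,
7,Meadow Bunting,Emberiza cioides,Emci,song,,
8,Japanese Tit,Parus minor,Pami,song,Pova,E
9,Lesser Cuckoo,Cuculus poliocephalus,Cupo,song,,
10,Japanese White-eye,Zosterops japonicus,Zoja,song,,
11,Carrion Crow,Corvus corone,Coco,call,Coma,E
12,Oriental Greenfinch,Chloris sinica,Chsi,song,,
13,Oriental Reed Warbler,Acrocephalus orientalis,Acor,song,,
14,Eurasian Skylark,Alauda arvensis,Alar,song,,
15,Japanese Wagtail,Motacilla grandis,Mogr,song,Moal,D
16,Barn Swallow,Hirundo rustica,Hiru,call,,
17,White Wagtail,Motacilla alba,Moal,song,Mogr,D
18,Oriental Turtle Dove,Streptopelia orientalis,Stor,call,,
19,Grey Wagtail,Motacilla cinerea,Moci,song,,
20,Varied Tit,Poecile varius,Pova,song,Pami,E
21,Japanese Green Woodpecker,Picus awokera,Piaw,call,,
22,Common Cuckoo,Cuculus canorus,Cuca,song,,
23,Asian Stubtail,Urosphena squameiceps,Ursq,song,,
24,White-cheeked Starling,Spodiopsar cineraceus,Spci,call,,
25,Narcissus Flycatcher,Ficedula narcissina,Fina,song,Gaca,E
26,Japanese Pygmy Woodpecker,Dendrocopos kizuki,Deki,call,,
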