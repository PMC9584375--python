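code,site,level,species,so_total,nm_total,am_total,so_max_visit,nm_max_visit,am_max_visit,so_max_passes,nm_max_passes,am_max_passes
SE 1,Gura Dobrogei cave,1,Miniopterus schreibersii,49,29,504,49,26,504,100,100,100
SE 1,Gura Dobrogei cave,1,Myotis myotis/blythii,7,338,0,7,87,0,100,100,100
SE 1,Gura Dobrogei cave,1,Rhinolophus ferrumequinum,13,223,1,13,45,1,100,100,100
SE 1,Gura Dobrogei cave,1,Rhinolophus mehelyi,0,2,0,0,1,0,100,100,100
SE 2,Canara Tunnel,1,Miniopterus schreibersii,0,338,0,0,338,0,100,100,100
SE 2,Canara Tunnel,1,Myotis myotis/blythii,0,5,0,0,3,0,100,100,100
SE 2,Canara Tunnel,1,Rhinolophus ferrumequinum,0,118,0,0,58,0,100,100,100
SE 2,Canara Tunnel,1,Rhinolophus hipposideros,0,4,0,0,2,0,100,100,100
SE 2,Canara Tunnel,1,Rhinolophus mehelyi,0,7,0,0,6,0,100,100,100
SE 3,Hagieni Tunnel,1,Miniopterus schreibersii,0,449,0,0,448,0,100,100,100
SE 4,Valea Cetatii cave,1,Myotis myotis/blythii,0,8,0,0,6,0,942,21941,585
SE 4,Valea Cetatii cave,1,Rhinolophus ferrumequinum,2,22,0,2,11,0,942,21941,585
SE 4,Valea Cetatii cave,1,Rhinolophus hipposideros,3,5,0,3,3,0,942,21941,585
SE 5,Muierilor cave,1,Miniopterus schreibersii,1363,929,0,1363,883,0,11856,66459,9740
SE 5,Muierilor cave,1,Myotis myotis/blythii,11,7,0,11,5,0,11856,66459,9740
SE 5,Muierilor cave,1,Rhinolophus ferrumequinum,875,2061,70,875,1112,70,11856,66459,9740
SE 5,Muierilor cave,1,Rhinolophus hipposideros,20,82,1,20,49,1,11856,66459,9740
SE 6,Polovragi cave,1,Miniopterus schreibersii,0,7,0,0,7,0,3032,5330,10929
SE 6,Polovragi cave,1,Myotis myotis/blythii,5,18,3,5,13,3,3032,5330,10929
SE 6,Polovragi cave,1,Rhinolophus ferrumequinum,416,542,0,416,283,0,3032,5330,10929
SE 6,Polovragi cave,1,Rhinolophus hipposideros,11,29,1,11,16,1,3032,5330,10929
SE 7,Stogu cave,1,Myotis myotis/blythii,0,3,0,0,3,0,100,100,100
SE 7,Stogu cave,1,Rhinolophus ferrumequinum,0,28,9,0,28,9,100,100,100
SE 7,Stogu cave,1,Rhinolophus hipposideros,0,7,3,0,7,3,100,100,100
SE 8,Lacul Verde cave,1,Myotis myotis/blythii,0,3,7,0,3,7,100,100,100
SE 8,Lacul Verde cave,1,Rhinolophus ferrumequinum,0,34,33,0,34,33,100,100,100
SE 8,Lacul Verde cave,1,Rhinolophus hipposideros,0,4,1,0,4,1,100,100,100
SE 9,Closani cave,1,Rhinolophus euryale,246,342,22,246,255,22,100,100,100
SE 9,Closani cave,1,Rhinolophus ferrumequinum,21,63,0,21,15,0,100,100,100
SE 9,Closani cave,1,Rhinolophus hipposideros,0,1,0,0,1,0,100,100,100
SE 10,Meziad cave,1,Miniopterus schreibersii,2,2002,384,2,1230,384,2778,1334,2531
SE 10,Meziad cave,1,Myotis myotis/blythii,3,4,0,3,3,0,2778,1334,2531
SE 10,Meziad cave,1,Nyctalus noctula,0,1,0,0,1,0,2778,1334,2531
SE 10,Meziad cave,1,Pipistrellus pipistrellus,230,1,0,230,1,0,2778,1334,2531
SE 10,Meziad cave,1,Rhinolophus ferrumequinum,264,504,1,264,281,1,2778,1334,2531
SE 10,Meziad cave,1,Rhinolophus hipposideros,3,138,2,3,94,2,2778,1334,2531
SE 10,Meziad cave,2,Miniopterus schreibersii,0,0,1,0,0,1,2778,1334,2531
SE 10,Meziad cave,2,Myotis myotis/blythii,0,2,279,0,1,279,2778,1334,2531
SE 10,Meziad cave,2,Nyctalus noctula,0,42,0,0,42,0,2778,1334,2531
SE 10,Meziad cave,2,Rhinolophus ferrumequinum,27,7,1,27,4,1,2778,1334,2531
SE 10,Meziad cave,2,Rhinolophus hipposideros,3,1,10,3,1,10,2778,1334,2531
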