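code,name,analysed_period,cavity_type,altitude_m,n_levels,cave_length_m,touristic_length_m,tourist_passes_per_year
SE 1,Gura Dobrogei cave,2012-2014,wild_cave,49,3,451,,100
SE 2,Canara Tunnel,2012-2014,artificial,36,1,282,,100
SE 3,Hagieni Tunnel,2012-2014,artificial,21,1,150,,100
SE 4,Stogu cave,2010-2012,wild_cave,939,2,240,,100
SE 5,Lacul Verde cave,2010-2012,wild_cave,992,2,183,,100
SE 6,Polovragi cave,2014-2016,show_cave,630,3,10350,500,52835
SE 7,Muierilor cave,2014-2016,show_cave,645,3,8000,800,407636
SE 8,Closani cave,2014-2016,wild_cave,433,2,1458,,100
SE 9,Valea Cetatii cave,2014-2016,show_cave,825,2,958,120,22135
SE 10,Meziad cave,2014-2016,show_cave,435,2,6000,1000,14266
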