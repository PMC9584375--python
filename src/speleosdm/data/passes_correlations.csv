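species,so_rho,so_p,nm_rho,nm_p,am_rho,am_p
Miniopterus schreibersii,0.41,0.40,0.21,0.68,-0.28,0.58
Myotis myotis/blythii,0.61,0.10,0.44,0.27,0.29,0.48
Rhinolophus ferrumequinum,0.81,<0.05,0.38,0.30,0.02,0.94
Rhinolophus hipposideros,1,<0.05,0.53,0.17,0.29,0.48
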