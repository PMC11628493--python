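region,organ,abbreviation,surface_mm2,volume_mm3
visual receptors,retinula,Re,9.0455,0.0709
visual receptors,rhabdom,Rh,1.1306,0.0167
visual neuropils,lamina,La,0.4719,0.0068
visual neuropils,external_medulla,Me,0.2413,0.0036
visual neuropils,lobula,Lo,0.1093,0.0014
protocerebrum,hemiellipsoid_body_neuropil,HN,4.2511,0.2924
protocerebrum,terminal_medulla_neuropil,TM,1.3099,0.0594
protocerebrum,anterior_medial_protocerebral_neuropil,AMPN,0.7948,0.0365
protocerebrum,posterior_medial_protocerebral_neuropil,PMPN,0.5265,0.0179
deutocerebrum,olfactory_lobe,OL,2.0031,0.0590
deutocerebrum,lateral_antennular_neuropil,LAN,0.5809,0.0124
deutocerebrum,median_antennular_neuropil,MAN,0.0534,0.0007
tritocerebrum,antenna_ii_neuropil,AnN,0.9321,0.0299
tract,olfactory_globular_tract,OGT,0.5819,0.0066
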