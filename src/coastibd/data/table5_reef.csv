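region,total_surveys,sightings,sf_pct,index
"BC: Western Vancouver Island (Fredericksen Pt-Cape Beale)",760,465,61.2,2.6
"BC: Barkley Sound (Ucluelet-Cape Beale)",719,447,62.2,2.6
"WA: Olympic Peninsula",1241,969,78.1,2.9
"Oregon",903,550,60.9,2.7
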