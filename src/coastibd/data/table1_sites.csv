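site_id,region,name,lat,lon,n,years
1,"OR, USA","Rogue Reef, Island Rock, Orford Reef",42.66307,-124.47880,77,2005
2,"OR, USA","Till Rock, Newport",44.61870,-124.09228,50,2009
3,"OR, USA","Cannon Beach",45.89057,-123.96157,47,2009
4,"WA, USA","Northwest Westport",47.57043,-124.44843,54,2009
5,"WA, USA","Tatoosh",48.39132,-124.73900,35,"2008,2010"
6,"BC, Canada","Barkley Sound",48.84603,-125.33147,175,"2007-2010"
7,"BC, Canada","Kyuquot and Checleset Bay",50.01132,-127.34550,55,2010
8,"BC, Canada","Quatsino Sound",50.43517,-127.98047,49,2009
9,"BC, Canada","Gwaii Haanas",52.12028,-131.17255,30,2010
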