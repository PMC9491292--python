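# SYNTHETIC stand-in for the 73-type land-cover to 11-category dry-deposition
# mapping used by global models (the published Olson-based table is not
# redistributed here).  The mapping is total: each of the 73 source type ids
# maps to exactly one of the 11 categories.  Edit freely; consumers only
# require totality.
source_type,category
0,water
1,urban
2,agricultural
3,agricultural
4,agricultural
5,agricultural
6,agricultural
7,agricultural
8,agricultural
9,grassland_savanna
10,grassland_savanna
11,grassland_savanna
12,grassland_savanna
13,grassland_savanna
14,grassland_savanna
15,grassland_savanna
16,grassland_savanna
17,deciduous_forest
18,deciduous_forest
19,deciduous_forest
20,deciduous_forest
21,deciduous_forest
22,deciduous_forest
23,deciduous_forest
24,deciduous_forest
25,coniferous_forest
26,coniferous_forest
27,coniferous_forest
28,coniferous_forest
29,coniferous_forest
30,coniferous_forest
31,coniferous_forest
32,coniferous_forest
33,tropical_rainforest
34,tropical_rainforest
35,tropical_rainforest
36,tropical_rainforest
37,tropical_rainforest
38,tropical_rainforest
39,tropical_rainforest
40,tropical_rainforest
41,shrubland
42,shrubland
43,shrubland
44,shrubland
45,shrubland
46,shrubland
47,shrubland
48,tundra
49,tundra
50,tundra
51,tundra
52,tundra
53,tundra
54,tundra
55,desert_barren
56,desert_barren
57,desert_barren
58,desert_barren
59,desert_barren
60,desert_barren
61,desert_barren
62,wetland
63,wetland
64,wetland
65,wetland
66,wetland
67,wetland
68,water
69,water
70,water
71,water
72,water
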