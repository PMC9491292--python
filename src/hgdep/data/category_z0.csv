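# Default roughness length z0 (m) per dry-deposition land category.
category,z0
deciduous_forest,1.0
coniferous_forest,1.0
tropical_rainforest,2.0
agricultural,0.1
grassland_savanna,0.05
shrubland,0.05
tundra,0.03
desert_barren,0.002
wetland,0.1
urban,1.0
water,0.0001
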