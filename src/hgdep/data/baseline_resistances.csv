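# Seasonal baseline surface resistances (s m-1) per dry-deposition land
# category, after the Wesely (1989) big-leaf tabulation, with categories
# renamed/adapted to the 11-category set used by global Hg models (tropical
# rainforest carries evergreen-broadleaf values year-round).  9999 marks a
# blocked pathway (infinite resistance).  Seasonal classes:
#   1 midsummer (lush vegetation), 2 autumn (unharvested cropland),
#   3 late autumn (post frost, no snow), 4 winter (snow/subfreezing),
#   5 transitional spring (partial green-up).
# Columns: ri minimum bulk stomatal (water vapour); rlu upper-canopy cuticle
# (reference gas); rac in-canopy aerodynamic; rgs_so2/rgs_o3 ground;
# rcl_so2/rcl_o3 lower canopy (exposed surfaces), for the SO2/O3 references.
category,season,ri,rlu,rac,rgs_so2,rgs_o3,rcl_so2,rcl_o3
deciduous_forest,1,70,2000,2000,500,200,2000,1000
deciduous_forest,2,9999,9000,1500,500,200,9000,400
deciduous_forest,3,9999,9000,1000,500,200,9000,400
deciduous_forest,4,9999,9999,1000,100,3500,9000,400
deciduous_forest,5,140,4000,1200,500,200,4000,500
coniferous_forest,1,130,2000,2000,500,200,2000,1000
coniferous_forest,2,250,4000,2000,500,200,2000,1000
coniferous_forest,3,250,4000,2000,500,200,3000,1000
coniferous_forest,4,400,6000,2000,100,3500,200,1500
coniferous_forest,5,250,2000,2000,500,200,2000,1500
tropical_rainforest,1,70,2000,2000,500,200,2000,1000
tropical_rainforest,2,70,2000,2000,500,200,2000,1000
tropical_rainforest,3,70,2000,2000,500,200,2000,1000
tropical_rainforest,4,70,2000,2000,500,200,2000,1000
tropical_rainforest,5,70,2000,2000,500,200,2000,1000
agricultural,1,60,2000,200,150,150,2000,1000
agricultural,2,9999,9000,150,200,150,9000,400
agricultural,3,9999,9999,10,150,150,9999,1000
agricultural,4,9999,9999,10,100,3500,9999,1000
agricultural,5,120,4000,50,150,150,4000,1000
grassland_savanna,1,120,2000,100,350,200,2000,1000
grassland_savanna,2,9999,9000,100,350,200,9000,400
grassland_savanna,3,9999,9000,100,350,200,9000,400
grassland_savanna,4,9999,9999,10,100,3500,9999,1000
grassland_savanna,5,240,4000,80,350,200,4000,500
shrubland,1,150,4000,200,400,200,4000,1000
shrubland,2,9999,9000,140,400,200,9000,400
shrubland,3,9999,9000,120,400,200,9000,600
shrubland,4,9999,9000,50,50,3500,9000,800
shrubland,5,300,8000,120,400,200,8000,800
tundra,1,200,4000,100,400,200,4000,1000
tundra,2,9999,9000,100,400,200,9000,600
tundra,3,9999,9000,50,400,200,9000,600
tundra,4,9999,9000,10,50,3500,9000,800
tundra,5,400,8000,60,400,200,8000,800
desert_barren,1,9999,9999,0,1000,400,9999,9999
desert_barren,2,9999,9999,0,1000,400,9999,9999
desert_barren,3,9999,9999,0,1000,400,9999,9999
desert_barren,4,9999,9999,0,1000,400,9999,9999
desert_barren,5,9999,9999,0,1000,400,9999,9999
wetland,1,80,2500,300,50,1000,2500,1000
wetland,2,9999,9000,200,50,800,9000,400
wetland,3,9999,9000,100,50,1000,9000,800
wetland,4,9999,9000,50,100,3500,9000,800
wetland,5,160,4000,200,50,1000,4000,600
urban,1,9999,9999,100,400,300,9999,9999
urban,2,9999,9999,100,400,300,9999,9999
urban,3,9999,9999,100,400,300,9999,9999
urban,4,9999,9999,100,100,600,9999,9999
urban,5,9999,9999,100,500,300,9999,9999
water,1,9999,9999,0,50,2000,9999,9999
water,2,9999,9999,0,50,2000,9999,9999
water,3,9999,9999,0,50,2000,9999,9999
water,4,9999,9999,0,50,2000,9999,9999
water,5,9999,9999,0,50,2000,9999,9999
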