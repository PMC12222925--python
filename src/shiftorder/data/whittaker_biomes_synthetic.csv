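# Synthetic approximation of the Whittaker biome diagram, digitized by hand
# for this package as straight-sided polygons in the mean-annual-temperature
# (degC) x annual-precipitation (mm) plane, covering -15..30 degC x 0..4500 mm.
# It is NOT a copy of any published polygon dataset; boundaries follow the
# classic diagram only approximately. Points falling in an overlap are
# assigned to the lowest biome id; points outside every polygon are assigned
# by nearest boundary and flagged as extrapolated.
biome_id,biome_name,vertex,temp_c,precip_mm
1,Tundra,1,-15,0
1,Tundra,2,-5,0
1,Tundra,3,-5,600
1,Tundra,4,-15,600
2,Boreal forest,1,-5,200
2,Boreal forest,2,3,200
2,Boreal forest,3,3,1300
2,Boreal forest,4,-5,1300
3,Temperate seasonal forest,1,3,550
3,Temperate seasonal forest,2,20,800
3,Temperate seasonal forest,3,20,2300
3,Temperate seasonal forest,4,3,1300
4,Temperate rain forest,1,3,1300
4,Temperate rain forest,2,20,2300
4,Temperate rain forest,3,20,4200
4,Temperate rain forest,4,3,2400
5,Tropical rain forest,1,20,2300
5,Tropical rain forest,2,30,2400
5,Tropical rain forest,3,30,4500
5,Tropical rain forest,4,20,4500
6,Tropical seasonal forest/savanna,1,20,800
6,Tropical seasonal forest/savanna,2,30,600
6,Tropical seasonal forest/savanna,3,30,2400
6,Tropical seasonal forest/savanna,4,20,2300
7,Subtropical desert,1,18,0
7,Subtropical desert,2,30,0
7,Subtropical desert,3,30,600
7,Subtropical desert,4,20,800
7,Subtropical desert,5,18,550
8,Temperate grassland/desert,1,-5,0
8,Temperate grassland/desert,2,18,0
8,Temperate grassland/desert,3,18,300
8,Temperate grassland/desert,4,3,450
8,Temperate grassland/desert,5,-5,200
9,Woodland/shrubland,1,3,450
9,Woodland/shrubland,2,18,300
9,Woodland/shrubland,3,20,800
9,Woodland/shrubland,4,3,550
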