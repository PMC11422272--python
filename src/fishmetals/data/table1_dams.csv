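dam_id,name,river,area_ha,capacity_Mm3,water_temp_c,fishermen,annual_production_t,mining_sites,basin_group,geothermal
1,Luis Donaldo Colosio/Huites,El Fuerte,9317,4568,16-31,274,38-400,55,fuerte-alamos,true
2,Miguel Hidalgo C./El Mahone,El Fuerte,12200,3600,16-29,244,236-2000,55,fuerte-alamos,true
3,Josefa Ortiz D./El Sabino,Alamos,5200,607,18-29,261,18-1940,55,fuerte-alamos,true
4,Guillermo Blake/El Sabinal,Ocoroni,2700,350,,,,8,ocoroni,false
5,Gustavo Diaz O./Bacurato,Sinaloa,7000,2900,18-32,136,450-1400,19,sinaloa,false
6,Eustaquio Buelna/Guamuchil,Mocorito,4700,344,20-32,67,5-200,5,mocorito,false
7,Adolfo Lopez M./El Varejonal,Humaya,11300,3160,19-31,229,100-1200,20,humaya,false
8,Sanalona,Tamazula,4500,845,20-31,103,40-900,5,tamazula,false
9,Jose Lopez P./El Comedero,San Lorenzo,9200,3400,21-31,197,<100-1100,16,san-lorenzo,false
10,Aurelio Benassini V./El Salto,Elota,3200,410,21-32,203,300-1800,5,elota,false
11,Picachos,Presidio,2100,328,21-31,214,289-864,6,presidio,false
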