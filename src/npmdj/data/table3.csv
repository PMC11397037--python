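dish_id,category,name,scenario,food_weight_excl_water_g,total_food_weight_g,energy_pts,satfat_pts,sugars_pts,sodium_pts,baseline,v_pts,protein_pts,fiber_pts,final_score
udon,staple,Udon (thick wheat noodles),left_all,332,473,3,0,2,10,15,0,0,5,10
udon,staple,Udon (thick wheat noodles),half,345,564,4,0,2,13,19,0,0,5,14
udon,staple,Udon (thick wheat noodles),all,358,658,4,0,3,17,24,0,0,5,19
tempura_udon,staple,Tempura udon,left_all,375,524,5,1,2,10,18,0,0,5,13
tempura_udon,staple,Tempura udon,half,388,615,5,1,2,14,22,0,0,5,17
tempura_udon,staple,Tempura udon,all,401,709,5,1,3,18,27,0,0,5,22
zaru_soba,staple,Zaru soba (cold buckwheat noodles),left_all,317,362,4,0,1,6,11,0,6,6,-1
zaru_soba,staple,Zaru soba (cold buckwheat noodles),half,321,378,4,0,1,7,12,0,6,6,0
zaru_soba,staple,Zaru soba (cold buckwheat noodles),all,337,437,4,0,2,11,17,0,0,6,11
ramen,staple,Ramen (soy sauce),left_all,249,316,3,0,0,7,10,0,4,8,-2
ramen,staple,Ramen (soy sauce),half,262,422,4,0,0,16,20,0,0,8,12
ramen,staple,Ramen (soy sauce),all,275,525,4,0,0,24,28,0,0,8,20
roast_pork_ramen,staple,Roasted pork ramen,left_all,310,377,4,1,0,11,16,0,0,8,8
roast_pork_ramen,staple,Roasted pork ramen,half,323,483,4,1,0,19,24,0,0,8,16
roast_pork_ramen,staple,Roasted pork ramen,all,336,586,5,1,0,27,33,0,0,8,25
tenshin,mixed_with_staple,Tenshin noodles (crab omelet on ramen),left_all,451,518,6,7,1,19,33,0,0,8,25
tenshin,mixed_with_staple,Tenshin noodles (crab omelet on ramen),half,464,624,7,7,1,28,43,0,0,8,35
tenshin,mixed_with_staple,Tenshin noodles (crab omelet on ramen),all,477,727,7,7,1,30,45,0,0,8,37
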