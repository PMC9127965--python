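food_id,name,category,serving_g,energy_kcal,carbohydrate_g,fiber_g,protein_g,fat_g,iauc_mean,iauc_sd,gi_mean,gi_sd,gi_class,gl_mean,gl_sd,gl_class,egl,n_subjects
bulgogi_croquette,Bulgogi croquette,Bread,80,220,25,2,9,10,1843,775,52,29,low,12,7,medium,13,8
sponge_cake,Sponge cake,Bread,30,105,18,0,2,2.8,1636,412,44,11,low,8,2,low,13,8
balance_shake,Balance shake,Calorie controlled meal,60,230,31,9,20,5,1304,758,35,18,low,8,4,low,10,8
sweet_potato_meal_cold,Sweet potato healthy meal (Cold),Calorie controlled meal,150,185,34,0,4,3.8,2767,969,52,23,low,18,8,medium,19,8
sweet_potato_meal_hot,Sweet potato healthy meal (Hot),Calorie controlled meal,150,185,34,0,4,3.8,2348,1077,42,17,low,14,6,medium,19,8
tofu_lentil_rice_meal,Tofu lentil-rice meal,Calorie controlled meal,210,340,50,0,19,8,2503,816,68,28,medium,34,14,high,22,8
cereal,Cereal,Cereal,40,150,35,0,2,0,3026,976,83,37,high,29,13,high,20,8
whole_grain_cereal,Whole-grain cereal,Cereal,40,169,30,1.9,2.9,4.7,2514,612,69,25,medium,19,7,medium,16,8
dumplings_kimchi,Dumplings with kimchi; frozen,Dumpling,220,407.5,40,5.5,15.5,22.0,1749,713,31,12,low,11,4,medium,13,8
dumplings_meat,Dumplings with meat; frozen,Dumpling,200,467.5,50,1.5,19.5,21.5,3643,1172,58,12,medium,28,6,high,18,8
bibimbap,Bibimbap; frozen,Easy cooked rice,217,315,58,7,6,8,4406,2319,73,36,high,37,18,high,24,8
fried_rice_hamburger,Fried rice with hamburger steak; frozen,Easy cooked rice,275,535,69,7,14,24,3258,1103,52,13,low,32,8,high,24,8
fried_rice_shrimp,Fried rice with shrimp; frozen,Easy cooked rice,225,375,63,2,7,11,3880,1299,74,26,high,45,16,high,28,8
cheese_sausage_hot_dog,Cheese and sausage hot dog,Hot dog,80,230,28,2,6,11,1885,518,35,10,low,9,3,low,14,8
cream_pasta,Cream pasta,Noodle,331.2,560,58,2,16,30,1429,413,37,7,low,21,4,high,20,8
spicy_noodle,Spicy noodle,Noodle,186.5,135,25,2,1,3.7,1127,550,31,14,low,7,3,low,15,8
tomato_pasta,Tomato pasta,Noodle,270,290,53,4,10,5,1901,809,55,34,low,27,17,high,24,8
beef_mushroom_porridge,Beef and mushroom rice porridge,Porridge,250,155,26,3,7,13,2451,700,65,19,medium,15,4,medium,12,8
red_bean_porridge,Red bean porridge,Porridge,250,205,46,10,9,0.5,2589,1325,68,35,medium,24,13,high,19,8
corn_salad,Corn salad,Salad,115,100,18,3,2,4.8,1172,315,23,8,low,4,1,low,11,8
almond_cookies,Almond cookies,Snack,80,420,48,0,8,22,1757,939,47,28,low,23,14,high,20,8
dried_tofu_snack,Dried tofu snack,Snack,65,310,36,0,6,16,2445,554,67,25,medium,24,9,high,17,8
button_mushroom_soup,Button mushroom soup,Soup,190,165,13,2,4,11,1135,194,31,11,low,3,1,low,8,8
wheat_noodle_tteokbokki,Wheat noodle tteokbokki,Tteokbokki,140,430,91,3.3,11.1,3,2716,1134,50,17,low,44,15,high,39,8
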