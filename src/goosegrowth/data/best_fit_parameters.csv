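trait,unit,breed,model,A,B,k,r_squared,inflexion_age,inflection_value
body weight,g,shitou,logistic,5290.870,37.334,0.608,0.999,5.954,2645.435
body weight,g,wuzong,logistic,2692.975,23.443,0.638,0.998,4.944,1346.488
body length,cm,shitou,logistic,41.720,4.421,0.344,0.995,4.321,20.860
body length,cm,wuzong,von_bertalanffy,33.649,0.420,0.204,0.989,1.133,9.970
chest depth,cm,shitou,logistic,13.486,3.724,0.369,0.987,3.563,6.743
chest depth,cm,wuzong,logistic,10.982,3.041,0.365,0.998,3.047,5.491
chest width,cm,shitou,logistic,16.465,5.411,0.350,0.995,4.824,8.233
chest width,cm,wuzong,logistic,11.972,3.966,0.388,0.996,3.551,5.986
pelvis width,cm,shitou,logistic,11.298,3.569,0.409,0.980,3.111,5.649
pelvis width,cm,wuzong,logistic,8.580,2.603,0.445,0.987,2.150,4.290
keel length,cm,shitou,logistic,21.676,6.438,0.329,0.993,5.660,10.838
keel length,cm,wuzong,von_bertalanffy,18.558,0.501,0.165,0.995,2.469,5.499
tibia length,cm,shitou,logistic,10.385,2.387,0.451,0.992,1.929,5.193
tibia length,cm,wuzong,logistic,8.499,1.891,0.504,0.997,1.264,4.250
shank circumference,cm,shitou,logistic,5.835,1.982,0.420,0.994,1.629,2.918
shank circumference,cm,wuzong,logistic,4.405,1.529,0.554,0.996,0.766,2.203
semi-submersible length,cm,shitou,logistic,80.536,4.030,0.348,0.998,4.005,40.268
semi-submersible length,cm,wuzong,logistic,61.177,3.128,0.391,0.997,2.917,30.589
neck length,cm,shitou,logistic,28.192,3.455,0.369,0.996,3.360,14.096
neck length,cm,wuzong,logistic,21.191,2.891,0.429,0.996,2.475,10.596
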