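breed,trait,unit,week,value
shitou,body weight,g,0,123.55
shitou,body weight,g,1,194.60
shitou,body weight,g,2,415.32
shitou,body weight,g,3,775.65
shitou,body weight,g,4,1176.13
shitou,body weight,g,5,1966.10
shitou,body weight,g,6,2710.08
shitou,body weight,g,7,3444.15
shitou,body weight,g,8,4109.31
shitou,body weight,g,9,4594.38
shitou,body weight,g,10,4780.85
shitou,body weight,g,11,4989.92
shitou,body weight,g,12,5289.92
wuzong,body weight,g,0,65.39
wuzong,body weight,g,1,173.37
wuzong,body weight,g,2,337.80
wuzong,body weight,g,3,669.63
wuzong,body weight,g,4,911.83
wuzong,body weight,g,5,1390.37
wuzong,body weight,g,6,1786.33
wuzong,body weight,g,7,2146.17
wuzong,body weight,g,8,2317.60
wuzong,body weight,g,9,2503.88
wuzong,body weight,g,10,2545.63
wuzong,body weight,g,11,2612.32
wuzong,body weight,g,12,2743.04
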