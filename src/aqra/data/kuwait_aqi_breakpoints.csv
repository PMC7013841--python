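pollutant,category,index_low,index_high,conc_low,conc_high,window_hours
O3,Good,0,50,0.0,0.03,8
O3,Moderate,51,100,0.031,0.06,8
O3,Unhealthy (1),101,150,0.061,0.092,8
O3,Unhealthy (2),151,200,0.093,0.124,8
O3,Very Unhealthy,201,300,0.125,0.374,8
O3,Hazardous,301,500,0.375,0.504,8
PM10,Good,0,50,0.0,90,24
PM10,Moderate,51,100,90.1,350.0,24
PM10,Unhealthy (1),101,150,350.1,431.1,24
PM10,Unhealthy (2),151,200,431.4,512.5,24
PM10,Very Unhealthy,201,300,512.6,675.0,24
PM10,Hazardous,301,500,675.1,1000,24
CO,Good,0,50,0.0,4.0,8
CO,Moderate,51,100,4.1,8.0,8
CO,Unhealthy (1),101,150,8.1,11.7,8
CO,Unhealthy (2),151,200,11.8,15.4,8
CO,Very Unhealthy,201,300,15.5,30.4,8
CO,Hazardous,301,500,30.5,50.4,8
SO2,Good,0,50,0.0,0.03,24
SO2,Moderate,51,100,0.031,0.06,24
SO2,Unhealthy (1),101,150,0.061,0.182,24
SO2,Unhealthy (2),151,200,0.183,0.304,24
SO2,Very Unhealthy,201,300,0.305,0.604,24
SO2,Hazardous,301,500,0.605,1.004,24
NO2,Good,0,50,0.0,0.03,24
NO2,Moderate,51,100,0.04,0.05,24
NO2,Unhealthy (1),101,150,0.06,0.30,24
NO2,Unhealthy (2),151,200,0.31,0.55,24
NO2,Very Unhealthy,201,300,0.56,1.04,24
NO2,Hazardous,301,500,1.05,2.04,24
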