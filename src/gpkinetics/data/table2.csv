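model,feed_category,m,r,mu,a,p,r2,rmse,loglik,bic
Burr III,Compound,77.1,,,0.953,6.135,0.996,1.69,-15.4,37.4
Burr III,Corn,88.8,,,1.333,13.813,0.995,2.68,-19.7,45.9
Burr III,Processed protein,64.6,,,0.779,5.097,0.997,1.15,-11.7,29.9
Burr III,Legumes,78.0,,,1.172,6.074,0.998,1.41,-12.7,32.0
Burr III,Soft cereal,83.6,,,1.315,7.862,0.994,2.69,-19.5,45.7
Burr III,Others,74.5,,,0.960,5.644,0.996,1.87,-15.7,37.9
Burr XII,Compound,70.4,0.109,,1.463,1.485,0.999,1.04,-10.1,29.0
Burr XII,Corn,84.4,0.111,,2.097,2.15,0.998,1.64,-14.3,37.3
Burr XII,Processed protein,57.1,0.083,,1.183,2.226,0.999,0.74,-7.0,22.7
Burr XII,Legumes,76.8,0.241,,1.970,0.788,0.999,1.14,-9.6,27.9
Burr XII,Soft cereal,83.1,0.255,,2.459,0.592,0.996,2.48,-17.9,44.7
Burr XII,Others,71.9,0.193,,1.604,0.967,0.998,1.48,-13.2,35.2
Cauchy,Compound,65.9,0.279,7.926,,,0.969,5.06,-25.5,57.6
Cauchy,Corn,81.3,0.338,8.869,,,0.980,5.35,-26.0,58.5
Cauchy,Processed protein,50.5,0.232,8.404,,,0.961,4.25,-23.8,54.1
Cauchy,Legumes,71.5,0.392,5.939,,,0.969,5.40,-26.1,58.7
Cauchy,Soft cereal,77.4,0.459,5.954,,,0.974,5.56,-26.3,59.2
Cauchy,Others,64.3,0.306,7.099,,,0.967,4.95,-25.3,57.2
Dagum,Compound,70.2,0.108,,1.703,0.834,0.999,1.00,-9.7,28.2
Dagum,Corn,83.7,0.105,,2.409,0.867,0.998,1.59,-13.9,36.6
Dagum,Processed protein,56.7,0.157,,1.504,0.993,0.999,0.71,-6.5,21.8
Dagum,Legumes,75.9,0.644,,1.553,3.243,0.999,1.20,-10.0,28.8
Dagum,Soft cereal,81.6,0.637,,1.740,4.473,0.995,2.62,-18.5,45.7
Dagum,Others,70.2,0.311,,1.535,1.776,0.998,1.45,-13.2,35.2
Exponential 2p,Compound,68.2,0.085,,,,0.995,1.85,-16.8,37.9
Exponential 2p,Corn,86.0,0.071,,,,0.977,5.36,-26.7,57.8
Exponential 2p,Processed protein,51.8,0.082,,,,0.996,1.14,-12.3,29.0
Exponential 2p,Legumes,73.5,0.121,,,,0.988,3.06,-20.6,45.6
Exponential 2p,Soft cereal,80.6,0.116,,,,0.978,4.80,-25.5,55.5
Exponential 2p,Others,66.3,0.096,,,,0.992,2.36,-19.0,42.5
Exponential 3p,Compound,67.9,0.089,0.244,,,0.996,1.83,-16.0,38.6
Exponential 3p,Corn,85.0,0.080,0.817,,,0.983,4.90,-25.2,57.0
Exponential 3p,Processed protein,51.9,0.081,-0.042,,,0.997,1.16,-11.9,30.3
Exponential 3p,Legumes,73.3,0.127,0.253,,,0.990,3.05,-20.0,46.5
Exponential 3p,Soft cereal,80.2,0.125,0.401,,,0.981,4.78,-24.8,56.2
Exponential 3p,Others,66.2,0.099,0.164,,,0.992,2.42,-18.7,43.9
Exponentiated exponential,Compound,67.2,0.106,,1.233,,0.997,1.45,-14.0,34.6
Exponentiated exponential,Corn,81.9,0.148,,2.176,,0.997,2.10,-17.4,41.3
Exponentiated exponential,Processed protein,52.2,0.078,,0.971,,0.998,0.93,-10.1,26.8
Exponentiated exponential,Legumes,72.2,0.174,,1.522,,0.995,2.15,-17.4,41.5
Exponentiated exponential,Soft cereal,78.2,0.205,,1.942,,0.990,3.42,-21.8,50.2
Exponentiated exponential,Others,65.7,0.113,,1.189,,0.994,2.02,-17.2,41.0
Frechet,Compound,79.2,0.161,,0.850,,0.996,1.90,-16.5,39.6
Frechet,Corn,89.1,0.145,,1.294,,0.994,2.81,-20.1,46.8
Frechet,Processed protein,68.1,0.133,,0.666,,0.996,1.29,-12.7,31.9
Frechet,Legumes,79.2,0.237,,1.067,,0.997,1.57,-13.9,34.5
Frechet,Soft cereal,84.4,0.227,,1.226,,0.993,2.81,-19.9,46.5
Frechet,Others,76.5,0.182,,0.853,,0.995,2.02,-16.3,39.1
Generalized logistic,Compound,68.3,,,0.084,,0.991,2.47,-19.6,43.5
Generalized logistic,Corn,86.2,,,0.070,,0.974,5.70,-27.3,58.9
Generalized logistic,Processed protein,51.9,,,0.081,,0.993,1.58,-15.6,35.6
Generalized logistic,Legumes,73.7,,,0.118,,0.981,4.02,-23.6,51.6
Generalized logistic,Soft cereal,80.8,,,0.114,,0.971,5.54,-26.9,58.2
Generalized logistic,Others,66.5,,,0.095,,0.987,2.93,-21.1,46.6
Gompertz,Compound,67.6,0.083,,1.011,,0.996,1.81,-15.9,38.4
Gompertz,Corn,80.4,0.042,,1.139,,0.992,3.28,-21.4,49.3
Gompertz,Processed protein,54.3,0.081,,0.989,,0.997,1.02,-11.0,28.6
Gompertz,Legumes,72.8,0.106,,1.048,,0.992,2.72,-19.1,44.8
Gompertz,Soft cereal,77.9,0.088,,1.105,,0.984,4.39,-24.1,54.8
Gompertz,Others,67.9,0.091,,1.006,,0.994,2.15,-17.5,41.5
Gumbel,Compound,63.9,0.211,9.925,,,0.967,5.26,-25.8,58.3
Gumbel,Corn,79.2,0.247,10.594,,,0.983,4.95,-25.2,57.0
Gumbel,Processed protein,48.3,0.192,10.317,,,0.957,4.46,-24.2,55.0
Gumbel,Legumes,69.1,0.293,7.463,,,0.959,6.22,-27.3,61.2
Gumbel,Soft cereal,74.6,0.348,7.126,,,0.962,6.74,-28.0,62.7
Gumbel,Others,62.6,0.220,9.114,,,0.959,5.47,-26.2,59.0
Half Cauchy,Compound,75.2,0.114,0.283,,,0.997,1.60,-14.6,35.7
Half Cauchy,Corn,95.0,0.101,0.914,,,0.985,4.69,-24.8,56.2
Half Cauchy,Processed protein,57.6,0.103,-0.026,,,0.998,0.94,-10.0,26.6
Half Cauchy,Legumes,79.7,0.169,0.338,,,0.992,2.70,-18.1,42.9
Half Cauchy,Soft cereal,87.5,0.166,0.509,,,0.984,4.39,-24.0,54.6
Half Cauchy,Others,72.8,0.129,0.221,,,0.995,1.99,-16.3,39.1
Half logistic,Compound,66.4,0.140,,,,0.995,1.82,-16.8,38.0
Half logistic,Corn,83.4,0.118,,,,0.987,3.98,-24.0,52.4
Half logistic,Processed protein,50.4,0.134,,,,0.990,1.81,-16.3,37.1
Half logistic,Legumes,72.1,0.193,,,,0.990,2.83,-20.6,45.6
Half logistic,Soft cereal,78.9,0.187,,,,0.984,4.12,-24.2,52.7
Half logistic,Others,64.7,0.157,,,,0.990,2.42,-19.5,43.4
Inverse exponential,Compound,74.3,0.173,,,,0.993,2.14,-18.4,41.1
Inverse exponential,Corn,95.9,0.137,,,,0.991,3.27,-22.2,48.7
Inverse exponential,Processed protein,55.9,0.172,,,,0.986,2.32,-18.9,42.2
Inverse exponential,Legumes,79.9,0.239,,,,0.995,1.99,-16.5,37.4
Inverse exponential,Soft cereal,88.3,0.224,,,,0.990,3.13,-21.5,47.3
Inverse exponential,Others,72.1,0.195,,,,0.992,2.34,-19.0,42.4
Inverse paralogistic,Compound,72.4,0.158,,1.333,,0.998,1.15,-11.9,30.3
Inverse paralogistic,Corn,85.9,0.168,,1.726,,0.997,1.94,-16.7,39.9
Inverse paralogistic,Processed protein,58.2,0.121,,1.163,,0.998,0.82,-8.8,24.2
Inverse paralogistic,Legumes,75.8,0.244,,1.495,,0.998,1.20,-11.2,29.0
Inverse paralogistic,Soft cereal,81.5,0.252,,1.662,,0.995,2.51,-18.9,44.4
Inverse paralogistic,Others,70.5,0.174,,1.318,,0.997,1.57,-14.5,35.7
Logistic,Compound,64.3,0.289,7.879,,,0.978,4.31,-24.0,54.7
Logistic,Corn,79.6,0.328,8.834,,,0.989,3.91,-23.1,52.7
Logistic,Processed protein,48.9,0.248,8.286,,,0.968,3.79,-22.7,52.0
Logistic,Legumes,70.0,0.399,5.934,,,0.975,4.85,-25.1,56.7
Logistic,Soft cereal,75.9,0.445,5.957,,,0.977,5.31,-25.9,58.3
Logistic,Others,62.8,0.314,7.089,,,0.972,4.43,-24.3,55.2
Log-logistic,Compound,71.1,0.121,,1.500,,0.999,1.03,-10.9,28.4
Log-logistic,Corn,84.3,0.113,,2.094,,0.998,1.63,-15.1,36.7
Log-logistic,Processed protein,57.5,0.104,,1.251,,0.999,0.76,-8.1,22.8
Log-logistic,Legumes,74.9,0.174,,1.707,,0.998,1.24,-11.8,30.2
Log-logistic,Soft cereal,80.5,0.171,,1.954,,0.994,2.56,-19.1,44.8
Log-logistic,Others,69.5,0.134,,1.472,,0.997,1.49,-14.2,35.1
Paralogistic,Compound,69.8,0.090,,1.400,,0.999,1.03,-10.9,28.3
Paralogistic,Corn,82.8,0.074,,1.841,,0.998,1.76,-15.7,38.0
Paralogistic,Processed protein,56.7,0.087,,1.209,,0.999,0.73,-7.7,22.1
Paralogistic,Legumes,74.0,0.123,,1.531,,0.998,1.48,-13.3,33.2
Paralogistic,Soft cereal,79.5,0.115,,1.701,,0.993,2.89,-20.2,47.0
Paralogistic,Others,68.5,0.102,,1.369,,0.997,1.51,-14.4,35.3
Rayleigh 2p,Compound,63.2,0.160,,,,0.963,5.11,-26.2,56.9
Rayleigh 2p,Corn,79.5,0.138,,,,0.990,3.41,-22.5,49.4
Rayleigh 2p,Processed protein,47.6,0.157,,,,0.939,4.88,-25.7,55.7
Rayleigh 2p,Legumes,69.0,0.210,,,,0.965,5.13,-26.1,56.7
Rayleigh 2p,Soft cereal,75.6,0.204,,,,0.976,4.96,-25.9,56.2
Rayleigh 2p,Others,61.7,0.177,,,,0.956,5.16,-26.3,57.1
Rayleigh 3p,Compound,64.8,0.109,-3.120,,,0.986,3.34,-21.7,50.1
Rayleigh 3p,Corn,80.2,0.118,-1.347,,,0.994,2.92,-20.3,47.1
Rayleigh 3p,Processed protein,49.5,0.093,-4.502,,,0.978,3.10,-20.8,48.3
Rayleigh 3p,Legumes,70.5,0.152,-2.113,,,0.984,3.81,-22.9,52.3
Rayleigh 3p,Soft cereal,76.8,0.163,-1.391,,,0.984,4.43,-24.2,55.0
Rayleigh 3p,Others,63.3,0.120,-2.885,,,0.981,3.58,-22.3,51.3
Weibull,Compound,67.1,0.091,,1.114,,0.997,1.56,-14.6,35.9
Weibull,Corn,81.3,0.090,,1.554,,0.996,2.48,-18.8,44.2
Weibull,Processed protein,52.4,0.079,,0.967,,0.998,0.91,-9.9,26.3
Weibull,Legumes,72.2,0.129,,1.226,,0.994,2.35,-18.1,42.9
Weibull,Soft cereal,77.9,0.132,,1.414,,0.988,3.74,-22.6,51.9
Weibull,Others,65.8,0.099,,1.079,,0.994,2.06,-17.3,41.3
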