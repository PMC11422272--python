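dam_id,tissue,metal,mean,sd,basis
1,muscle,Cd,0.036,0.018,dw
1,muscle,Cu,7.1,0.6,dw
1,muscle,Zn,35.1,9.5,dw
1,liver,Cd,30.2,33.1,dw
1,liver,Cu,5662,5072,dw
1,liver,Zn,364,441,dw
2,muscle,Cd,0.030,0.012,dw
2,muscle,Cu,5.9,4.8,dw
2,muscle,Zn,37.5,7.1,dw
2,liver,Cd,17.6,13.6,dw
2,liver,Cu,5092,4005,dw
2,liver,Zn,418,18,dw
3,muscle,Cd,0.024,0.012,dw
3,muscle,Cu,3.15,1.78,dw
3,muscle,Zn,36.3,8.9,dw
3,liver,Cd,2.15,1.74,dw
3,liver,Cu,1790,1682,dw
3,liver,Zn,239,151,dw
4,muscle,Cd,0.024,0.006,dw
4,muscle,Cu,7.74,8.93,dw
4,muscle,Zn,35.1,5.9,dw
4,liver,Cd,9.59,6.41,dw
4,liver,Cu,3621,2964,dw
4,liver,Zn,294,143,dw
5,muscle,Cd,0.036,0.018,dw
5,muscle,Cu,14.3,13.1,dw
5,muscle,Zn,38.1,7.7,dw
5,liver,Cd,8.97,5.64,dw
5,liver,Cu,2703,2020,dw
5,liver,Zn,292,91,dw
6,muscle,Cd,0.024,0.012,dw
6,muscle,Cu,16.1,30.4,dw
6,muscle,Zn,28.0,5.4,dw
6,liver,Cd,7.49,6.87,dw
6,liver,Cu,574,564,dw
6,liver,Zn,145,73,dw
7,muscle,Cd,0.012,0.006,dw
7,muscle,Cu,14.3,25.6,dw
7,muscle,Zn,29.2,4.8,dw
7,liver,Cd,4.77,5.79,dw
7,liver,Cu,1349,1144,dw
7,liver,Zn,132,81,dw
8,muscle,Cd,0.018,0.006,dw
8,muscle,Cu,5.4,7.1,dw
8,muscle,Zn,34.5,8.3,dw
8,liver,Cd,6.92,5.44,dw
8,liver,Cu,1559,1097,dw
8,liver,Zn,170,105,dw
9,muscle,Cd,0.024,0.012,dw
9,muscle,Cu,13.1,24.4,dw
9,muscle,Zn,35.1,7.7,dw
9,liver,Cd,15.4,19.8,dw
9,liver,Cu,2303,2441,dw
9,liver,Zn,128,77,dw
10,muscle,Cd,0.042,0.018,dw
10,muscle,Cu,11.9,10.1,dw
10,muscle,Zn,33.3,7.1,dw
10,liver,Cd,4.10,2.72,dw
10,liver,Cu,1969,1277,dw
10,liver,Zn,241,105,dw
11,muscle,Cd,0.018,0.012,dw
11,muscle,Cu,4.2,4.8,dw
11,muscle,Zn,23.8,3.6,dw
11,liver,Cd,4.31,2.82,dw
11,liver,Cu,1036,744,dw
11,liver,Zn,89.2,37.9,dw
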