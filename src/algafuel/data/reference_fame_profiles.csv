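fatty_acid,Chlorella@0.08,Chlorella@0.20,Chlorella@0.30,Chlorella@0.38,Chlorella@0.45,Chlorella@0.50,Scenedesmus@0.10,Scenedesmus@0.20,Scenedesmus@0.30,Scenedesmus@0.40,Scenedesmus@0.50,Nitzschia@0.10,Nitzschia@0.20,Nitzschia@0.30,Tetraselmis@0.10,Tetraselmis@0.20,Tetraselmis@0.30,Tetraselmis@0.40,Tetraselmis@0.50,Tetraselmis@0.60,Tetraselmis@0.80,Tetraselmis@0.90
14:0,–,–,–,–,–,–,–,–,–,–,–,6.60,7.60,6.30,–,–,–,–,–,–,–,–
16:0,–,–,–,17.40,15.40,14.80,–,16.40,16.50,16.30,16.00,23.70,25.20,20.80,14.90,14.60,14.80,16.00,11.40,17.00,17.90,18.00
16:1n7,33.10,16.60,14.50,2.30,–,–,18.80,2.90,2.60,2.60,2.70,47.70,43.60,34.40,3.20,3.00,2.30,2.40,2.30,1.90,1.70,1.40
16:2n4,6.30,12.90,5.30,4.40,4.20,4.30,3.20,2.30,–,3.00,–,1.80,2.20,4.20,8.00,8.00,7.30,6.00,5.60,5.00,4.50,4.00
16:3n4,5.00,6.90,10.00,9.50,11.20,10.70,2.90,–,–,–,–,1.60,2.40,5.10,0.50,5.30,6.40,8.80,8.90,10.20,11.40,10.30
16:4n1,–,–,3.70,2.40,–,–,9.10,11.80,13.50,13.70,13.80,–,–,–,6.40,12.40,11.70,11.50,11.00,9.80,10.10,10.80
18:0,1.80,–,3.50,–,2.80,3.20,–,–,7.10,6.80,–,1.40,1.50,–,12.70,2.30,2.10,0.90,13.90,12.20,10.60,9.80
18:1n9,8.40,–,2.80,6.90,2.40,2.80,11.70,7.80,–,–,6.90,1.70,1.60,1.80,2.50,17.90,16.40,14.10,14.70,16.50,17.50,20.20
18:1n7,–,–,–,–,–,–,–,–,–,–,–,–,–,–,–,13.00,14.50,13.30,–,–,–,–
18:2n6,–,–,–,14.20,13.40,12.90,–,14.10,11.30,9.70,8.40,–,–,–,17.00,–,–,–,2.80,–,–,–
18:3n3,9.30,13.20,–,28.10,30.00,28.30,16.20,24.50,28.10,29.90,31.90,8.00,7.80,19.00,10.90,0.70,0.90,1.60,1.60,2.00,2.30,2.40
18:4n3,16.40,19.50,–,–,–,–,20.20,1.80,1.80,1.80,–,–,–,–,0.80,0.90,0.90,1.20,1.20,–,1.40,1.60
20:4n6,–,–,–,–,–,–,–,–,–,–,–,–,–,–,2.80,1.00,1.20,1.70,1.90,2.30,2.80,3.10
20:1n9,3.00,3.00,–,2.20,3.20,3.20,–,–,–,–,–,–,–,–,–,3.00,3.10,2.60,2.40,2.20,2.20,1.80
22:5n3,–,–,–,–,–,–,–,–,–,–,–,7.70,7.90,13.00,–,–,–,–,–,–,–,–
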