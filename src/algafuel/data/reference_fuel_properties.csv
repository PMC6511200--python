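property,Chlorella@0.08,Chlorella@0.20,Chlorella@0.30,Chlorella@0.38,Chlorella@0.45,Chlorella@0.50,Scenedesmus@0.10,Scenedesmus@0.20,Scenedesmus@0.30,Scenedesmus@0.40,Scenedesmus@0.50,Nitzschia@0.10,Nitzschia@0.20,Nitzschia@0.30,Tetraselmis@0.10,Tetraselmis@0.20,Tetraselmis@0.30,Tetraselmis@0.40,Tetraselmis@0.50,Tetraselmis@0.60,Tetraselmis@0.80,Tetraselmis@0.90
kinematic_viscosity,4.20,4.00,3.90,4.10,4.20,4.20,3.90,4.10,4.10,4.00,4.00,4.80,4.80,4.70,4.40,4.40,4.40,4.40,4.40,4.50,4.40,4.40
specific_gravity,0.88,0.88,0.88,0.88,0.88,0.88,0.88,0.88,0.88,0.88,0.88,0.87,0.87,0.87,0.87,0.87,0.87,0.87,0.87,0.87,0.87,0.87
cloud_point,-2.10,-4.60,-8.00,-2.90,-2.00,-1.00,-8.20,-2.90,-2.80,-4.00,-3.70,11.20,11.30,10.20,2.60,2.80,2.80,2.10,3.30,4.50,2.70,2.40
cetane_number,51.80,50.60,48.90,51.40,51.90,52.40,48.80,51.40,51.50,50.90,51.00,58.50,58.50,58.00,54.20,54.30,54.30,53.90,54.60,55.10,54.30,54.00
iodine_value,135.80,149.40,169.00,140.20,135.20,130.00,170.00,140.50,139.80,146.40,144.70,61.50,60.90,67.00,109.50,108.20,108.00,112.30,105.30,99.00,108.80,110.90
hhv,41.40,41.80,42.20,41.50,41.40,41.30,42.20,41.50,41.50,41.70,41.60,39.70,39.70,39.80,40.80,40.80,40.80,40.90,40.70,40.60,40.80,40.80
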