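class,Chlorella@0.08,Chlorella@0.20,Chlorella@0.30,Chlorella@0.38,Chlorella@0.45,Chlorella@0.50,Scenedesmus@0.10,Scenedesmus@0.20,Scenedesmus@0.30,Scenedesmus@0.40,Scenedesmus@0.50,Nitzschia@0.10,Nitzschia@0.20,Nitzschia@0.30,Tetraselmis@0.10,Tetraselmis@0.20,Tetraselmis@0.30,Tetraselmis@0.40,Tetraselmis@0.50,Tetraselmis@0.60,Tetraselmis@0.80,Tetraselmis@0.90
SFA,1.80,0.00,3.50,17.40,18.20,18.00,0.00,16.40,23.50,23.10,16.00,31.80,34.40,27.00,27.60,16.90,16.90,16.90,25.30,29.30,28.50,27.80
MUFA,44.50,19.60,19.40,11.40,5.60,3.20,30.50,10.70,2.60,2.60,9.60,49.60,45.20,36.20,5.80,37.00,36.40,32.40,19.40,20.60,21.40,23.50
PUFA,37.00,52.50,57.50,58.70,58.90,56.30,51.60,54.60,54.80,58.10,54.10,11.00,12.50,22.40,46.50,28.30,28.40,31.00,33.20,29.40,32.60,32.30
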