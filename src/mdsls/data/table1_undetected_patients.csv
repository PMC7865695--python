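subject_id,RBC,Hb,Hct,MCV,MCH,MCHC,RDW,Plt,MPV,WBC,% NE,% LY,% MO,% EO,% BA,Abs NE,Abs LY,Abs MO,Abs EO,Abs BA,% NRBC,Abs NRBC,MDS-LS
7,3.6,104,31.2,85.8,28.6,33.3,14.6,227,9.3,5.7,67.5,20.9,8.2,2.4,1.0,3.8,1.2,0.5,0.1,0.1,0.1,0.01,-6.5
17,3.2,109,32.0,100.6,34.3,34.1,15.0,146,11.3,7.4,83.4,7.4,8.3,0.4,0.5,6.2,0.5,0.6,0.0,0.0,0.0,0.00,-8.7
30,2.8,82,25.1,90.9,29.9,32.8,17.8,394,8.8,8.4,79.0,15.1,3.4,1.3,1.2,6.6,1.3,0.3,0.1,0.1,0.0,0.00,-54.4
35,2.6,81,24.3,93.1,31.0,33.3,16.6,373,9.4,8.4,74.8,10.0,10.4,2.5,2.3,6.3,0.8,0.9,0.2,0.2,0.3,0.02,-10.4
197,2.3,82,23.9,102.2,35.0,34.3,15.8,111,8.5,3.9,78.7,11.6,6.9,2.3,0.5,3.1,0.5,0.3,0.1,0.0,0.1,0.00,-16.5
199,2.7,87,27.3,101.2,32.3,31.9,16.9,383,7.8,8.2,79.0,10.7,7.1,2.6,0.6,6.5,0.9,0.6,0.2,0.0,0.2,0.02,-41.9
244,3.3,100,30.9,93.0,30.1,32.4,18.9,182,10.7,5.5,61.4,22.7,10.7,4.2,1.0,3.4,1.3,0.6,0.2,0.1,0.1,0.01,-23.1
245,4.4,130,38.7,87.4,29.2,33.5,15.4,104,10.8,5.3,76.5,8.5,12.8,1.6,0.6,4.0,0.5,0.7,0.1,0.0,0.1,0.00,-16.3
249,2.9,96,28.4,97.9,33.0,33.7,22.0,188,8.6,9.6,79.8,6.0,11.2,1.9,1.1,7.7,0.6,1.1,0.2,0.1,0.5,0.05,-4.0
253,3.8,114,34.9,92.6,30.3,32.7,14.3,257,8.6,4.5,46.0,39.9,10.2,3.5,0.4,2.1,1.8,0.5,0.2,0.0,0.1,0.01,-2.6
256,3.5,113,34.5,99.0,32.4,32.7,20.1,447,10.7,2.8,52.6,30.9,9.4,4.1,3.0,1.5,0.9,0.3,0.1,0.1,0.1,0.00,-21.5
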