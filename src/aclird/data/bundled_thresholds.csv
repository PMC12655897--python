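sex,task,frame,factor,direction,value
female,AGTT,IC,HK,above,0.6
female,AGTT,IC,HF,above,43.9
female,AGTT,IC,KF,below,31.7
female,AGTT,IC,AF,below,-10.9
female,AGTT,IC,KV,above,2.0
female,AGTT,IC,HA,above,9.9
female,AGTT,IC,HA,below,-10.0
female,AGTT,IC,HI,above,13.8
female,AGTT,IC,TIB,above,8.7
female,AGTT,IC,TCR,above,5.6
female,AGTT,pKF,HK,above,0.4
female,AGTT,pKF,HF,above,44.8
female,AGTT,pKF,KF,below,64.2
female,AGTT,pKF,AF,below,-16.5
female,AGTT,pKF,KV,above,2.1
female,AGTT,pKF,HA,above,9.8
female,AGTT,pKF,HA,below,-10.9
female,AGTT,pKF,HI,above,10.9
female,AGTT,pKF,TIB,above,8.3
female,AGTT,pKF,TCR,above,4.9
female,FS,IC,HK,above,0.0
female,FS,IC,HF,above,33.8
female,FS,IC,KF,below,24.8
female,FS,IC,AF,below,-23.1
female,FS,IC,KV,above,2.1
female,FS,IC,HA,above,8.0
female,FS,IC,HA,below,-7.0
female,FS,IC,HI,above,12.4
female,FS,IC,TIB,above,9.7
female,FS,IC,TCR,above,7.3
female,FS,pKF,HK,above,0.1
female,FS,pKF,HF,above,26.6
female,FS,pKF,KF,below,77.9
female,FS,pKF,AF,below,-21.5
female,FS,pKF,KV,above,3.2
female,FS,pKF,HA,above,7.9
female,FS,pKF,HA,below,-7.4
female,FS,pKF,HI,above,10.5
female,FS,pKF,TIB,above,8.0
female,FS,pKF,TCR,above,5.3
male,AGTT,IC,HK,above,0.7
male,AGTT,IC,HF,above,43.5
male,AGTT,IC,KF,below,32.2
male,AGTT,IC,AF,below,-10.7
male,AGTT,IC,KV,above,2.3
male,AGTT,IC,HA,above,10.3
male,AGTT,IC,HA,below,-7.8
male,AGTT,IC,HI,above,14.5
male,AGTT,IC,TIB,above,10.3
male,AGTT,IC,TCR,above,7.3
male,AGTT,pKF,HK,above,0.4
male,AGTT,pKF,HF,above,46.0
male,AGTT,pKF,KF,below,65.0
male,AGTT,pKF,AF,below,-16.6
male,AGTT,pKF,KV,above,1.4
male,AGTT,pKF,HA,above,10.4
male,AGTT,pKF,HA,below,-7.5
male,AGTT,pKF,HI,above,10.4
male,AGTT,pKF,TIB,above,8.6
male,AGTT,pKF,TCR,above,4.4
male,FS,IC,HK,above,0.0
male,FS,IC,HF,above,41.4
male,FS,IC,KF,below,26.2
male,FS,IC,AF,below,-22.8
male,FS,IC,KV,above,2.2
male,FS,IC,HA,above,8.1
male,FS,IC,HA,below,-2.9
male,FS,IC,HI,above,10.2
male,FS,IC,TIB,above,8.6
male,FS,IC,TCR,above,6.5
male,FS,pKF,HK,above,0.1
male,FS,pKF,HF,above,31.0
male,FS,pKF,KF,below,78.8
male,FS,pKF,AF,below,-23.8
male,FS,pKF,KV,above,2.4
male,FS,pKF,HA,above,8.0
male,FS,pKF,HA,below,-6.4
male,FS,pKF,HI,above,10.2
male,FS,pKF,TIB,above,7.1
male,FS,pKF,TCR,above,5.6
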