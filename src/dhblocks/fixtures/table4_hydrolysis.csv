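line,group,compound,mean,sd
DH005,HGSL,BITC,601.0,16.8
DH005,HGSL,4-PEITC,47.7,1.3
DH005,HGSL,2-PEITC,40.8,0.8
DH005,HGSL,SFN,20.24,1.33
DH005,HGSL,Total,709.8,16.7
DH014,HGSL,BITC,778.8,32.9
DH014,HGSL,4-PEITC,64.5,3.9
DH014,HGSL,2-PEITC,25.0,1.2
DH014,HGSL,SFN,2.03,0.15
DH014,HGSL,Total,870.3,37.6
DH016,HGSL,BITC,425.1,10.0
DH016,HGSL,4-PEITC,100.1,2.5
DH016,HGSL,2-PEITC,18.5,0.7
DH016,HGSL,SFN,2.90,0.13
DH016,HGSL,Total,546.6,12.5
DH017,HGSL,BITC,281.7,15.3
DH017,HGSL,4-PEITC,120.7,5.3
DH017,HGSL,2-PEITC,12.7,0.8
DH017,HGSL,SFN,2.35,0.21
DH017,HGSL,Total,417.5,21.5
DH026,HGSL,BITC,653.0,20.8
DH026,HGSL,4-PEITC,94.0,2.3
DH026,HGSL,2-PEITC,34.5,0.5
DH026,HGSL,SFN,2.39,0.15
DH026,HGSL,Total,783.9,23.5
pak_choi,control,BITC,108.9,2.7
pak_choi,control,4-PEITC,21.6,0.6
pak_choi,control,2-PEITC,8.1,0.2
pak_choi,control,SFN,0.57,0.04
pak_choi,control,Total,139.2,3.6
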