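line,group,compound,mean,sd
Chiffu,reference,GRA,,
Chiffu,reference,GAL,,
Chiffu,reference,SNG,,
Chiffu,reference,GNA,0.00,0.00
Chiffu,reference,GBN,0.00,0.00
Chiffu,reference,GNL,0.00,0.00
Chiffu,reference,PRO,0.38,0.00
Chiffu,reference,GBS,4.00,0.26
Chiffu,reference,4-MOGBS,1.09,0.04
Chiffu,reference,NGBS,3.16,0.52
Chiffu,reference,GNT,0.14,0.09
Chiffu,reference,Total,8.77,0.69
LP08,parent_high,GRA,0.11,0.05
LP08,parent_high,GAL,0.55,0.05
LP08,parent_high,SNG,0.17,0.00
LP08,parent_high,GNA,43.40,3.63
LP08,parent_high,GBN,0.66,0.06
LP08,parent_high,GNL,0.00,0.00
LP08,parent_high,PRO,0.71,0.06
LP08,parent_high,GBS,0.40,0.01
LP08,parent_high,4-MOGBS,0.31,0.04
LP08,parent_high,NGBS,0.76,0.06
LP08,parent_high,GNT,0.47,0.14
LP08,parent_high,Total,47.55,3.66
LP21,parent_low,GRA,0.00,0.00
LP21,parent_low,GAL,0.89,0.10
LP21,parent_low,SNG,0.00,0.00
LP21,parent_low,GNA,1.82,0.66
LP21,parent_low,GBN,0.00,0.00
LP21,parent_low,GNL,0.27,0.03
LP21,parent_low,PRO,0.88,0.09
LP21,parent_low,GBS,2.03,0.02
LP21,parent_low,4-MOGBS,0.63,0.03
LP21,parent_low,NGBS,3.44,0.24
LP21,parent_low,GNT,0.81,0.09
LP21,parent_low,Total,10.76,0.36
F1,F1,GRA,0.10,0.01
F1,F1,GAL,0.85,0.12
F1,F1,SNG,0.00,0.00
F1,F1,GNA,1.97,0.16
F1,F1,GBN,1.68,0.14
F1,F1,GNL,0.34,0.03
F1,F1,PRO,3.86,0.29
F1,F1,GBS,0.59,0.02
F1,F1,4-MOGBS,0.64,0.03
F1,F1,NGBS,4.58,0.16
F1,F1,GNT,0.47,0.05
F1,F1,Total,15.07,0.79
DH005,HGSL,GRA,1.23,0.18
DH005,HGSL,GAL,3.47,0.18
DH005,HGSL,SNG,0.05,0.01
DH005,HGSL,GNA,35.51,2.84
DH005,HGSL,GBN,0.63,0.04
DH005,HGSL,GNL,0.10,0.04
DH005,HGSL,PRO,0.22,0.03
DH005,HGSL,GBS,0.14,0.00
DH005,HGSL,4-MOGBS,0.06,0.00
DH005,HGSL,NGBS,2.03,0.20
DH005,HGSL,GNT,0.68,0.34
DH005,HGSL,Total,44.12,2.86
DH014,HGSL,GRA,0.07,0.02
DH014,HGSL,GAL,2.16,0.05
DH014,HGSL,SNG,0.05,0.01
DH014,HGSL,GNA,45.19,2.69
DH014,HGSL,GBN,7.13,0.62
DH014,HGSL,GNL,0.02,0.01
DH014,HGSL,PRO,0.06,0.02
DH014,HGSL,GBS,0.11,0.01
DH014,HGSL,4-MOGBS,0.10,0.01
DH014,HGSL,NGBS,0.77,0.04
DH014,HGSL,GNT,0.39,0.04
DH014,HGSL,Total,56.06,3.28
DH016,HGSL,GRA,0.12,0.07
DH016,HGSL,GAL,0.43,0.05
DH016,HGSL,SNG,0.11,0.07
DH016,HGSL,GNA,44.42,1.34
DH016,HGSL,GBN,1.68,0.07
DH016,HGSL,GNL,,
DH016,HGSL,PRO,0.57,0.37
DH016,HGSL,GBS,0.20,0.01
DH016,HGSL,4-MOGBS,0.16,0.01
DH016,HGSL,NGBS,0.76,0.02
DH016,HGSL,GNT,0.24,0.03
DH016,HGSL,Total,48.69,0.95
DH017,HGSL,GRA,0.07,0.01
DH017,HGSL,GAL,0.62,0.17
DH017,HGSL,SNG,0.08,0.02
DH017,HGSL,GNA,45.66,1.25
DH017,HGSL,GBN,2.70,0.09
DH017,HGSL,GNL,0.10,0.11
DH017,HGSL,PRO,0.32,0.03
DH017,HGSL,GBS,0.19,0.01
DH017,HGSL,4-MOGBS,0.19,0.02
DH017,HGSL,NGBS,0.50,0.02
DH017,HGSL,GNT,0.20,0.01
DH017,HGSL,Total,50.62,1.51
DH026,HGSL,GRA,0.09,0.02
DH026,HGSL,GAL,2.05,0.04
DH026,HGSL,SNG,0.07,0.04
DH026,HGSL,GNA,48.23,1.31
DH026,HGSL,GBN,5.39,0.25
DH026,HGSL,GNL,0.03,0.02
DH026,HGSL,PRO,0.05,0.00
DH026,HGSL,GBS,0.08,0.00
DH026,HGSL,4-MOGBS,0.11,0.00
DH026,HGSL,NGBS,0.57,0.05
DH026,HGSL,GNT,0.39,0.03
DH026,HGSL,Total,57.04,1.54
DH009,LGSL,GRA,0.04,0.03
DH009,LGSL,GAL,1.16,0.10
DH009,LGSL,SNG,0.00,0.00
DH009,LGSL,GNA,0.25,0.05
DH009,LGSL,GBN,0.26,0.07
DH009,LGSL,GNL,0.09,0.03
DH009,LGSL,PRO,0.82,0.26
DH009,LGSL,GBS,0.12,0.02
DH009,LGSL,4-MOGBS,0.10,0.01
DH009,LGSL,NGBS,0.33,0.03
DH009,LGSL,GNT,0.08,0.03
DH009,LGSL,Total,3.26,0.62
DH059,LGSL,GRA,0.06,0.01
DH059,LGSL,GAL,1.44,0.19
DH059,LGSL,SNG,0.01,0.01
DH059,LGSL,GNA,0.32,0.06
DH059,LGSL,GBN,0.52,0.08
DH059,LGSL,GNL,0.30,0.03
DH059,LGSL,PRO,1.97,0.23
DH059,LGSL,GBS,0.10,0.02
DH059,LGSL,4-MOGBS,0.07,0.01
DH059,LGSL,NGBS,0.38,0.03
DH059,LGSL,GNT,0.15,0.02
DH059,LGSL,Total,5.31,0.67
DH061,LGSL,GRA,,
DH061,LGSL,GAL,1.13,0.26
DH061,LGSL,SNG,0.01,0.01
DH061,LGSL,GNA,2.35,0.81
DH061,LGSL,GBN,1.70,0.64
DH061,LGSL,GNL,0.00,0.00
DH061,LGSL,PRO,0.05,0.01
DH061,LGSL,GBS,0.05,0.01
DH061,LGSL,4-MOGBS,0.01,0.00
DH061,LGSL,NGBS,0.11,0.02
DH061,LGSL,GNT,0.23,0.07
DH061,LGSL,Total,5.63,1.76
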