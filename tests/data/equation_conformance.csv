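equation,sex,age,serum_creatinine_umol,serum_cystatin_c,apply_race_term,expected_gfr
CKDEPI_CR_2009,male,25,61.88,0.6,false,131.1622028508
CKDEPI_CYS_2012,male,25,61.88,0.6,false,138.8927353972
CKDEPI_CRCYS_2012,male,25,61.88,0.6,false,139.7512556088
CKDEPI_CR_2021,male,25,61.88,0.6,false,131.1368611700
CKDEPI_CRCYS_2021,male,25,61.88,0.6,false,139.3090358415
EKFC_CR,male,25,61.88,0.6,false,116.5508645994
EKFC_CYS,male,25,61.88,0.6,false,119.1182117763
EKFC_CRCYS,male,25,61.88,0.6,false,117.8345381879
CKDEPI_CR_2009,male,50,123.76,1.5,false,58.1690453277
CKDEPI_CYS_2012,male,50,123.76,1.5,false,47.2359737790
CKDEPI_CRCYS_2012,male,50,123.76,1.5,false,51.5300661621
CKDEPI_CR_2021,male,50,123.76,1.5,false,61.2315613041
CKDEPI_CRCYS_2021,male,50,123.76,1.5,false,53.5426740966
EKFC_CR,male,50,123.76,1.5,false,59.2173042122
EKFC_CYS,male,50,123.76,1.5,false,49.6606915765
EKFC_CRCYS,male,50,123.76,1.5,false,54.4389978943
CKDEPI_CR_2009,male,80,84.0,0.85,false,75.2740559912
CKDEPI_CYS_2012,male,80,84.0,0.85,false,89.0499918885
CKDEPI_CRCYS_2012,male,80,84.0,0.85,false,83.8081127938
CKDEPI_CR_2021,male,80,84.0,0.85,false,80.8921397006
CKDEPI_CRCYS_2021,male,80,84.0,0.85,false,91.4650313851
EKFC_CR,male,80,84.0,0.85,false,67.9236818836
EKFC_CYS,male,80,84.0,0.85,false,75.1466125277
EKFC_CRCYS,male,80,84.0,0.85,false,71.5351472057
CKDEPI_CR_2009,female,25,63.65,0.81,false,116.3831604584
CKDEPI_CYS_2012,female,25,63.65,0.81,false,110.3027681422
CKDEPI_CRCYS_2012,female,25,63.65,0.81,false,112.4702308725
CKDEPI_CR_2021,female,25,63.65,0.81,false,118.9175473990
CKDEPI_CRCYS_2021,female,25,63.65,0.81,false,114.9934901192
EKFC_CR,female,25,63.65,0.81,false,104.1567251719
EKFC_CYS,female,25,63.65,0.81,false,108.1460574791
EKFC_CRCYS,female,25,63.65,0.81,false,106.1513913255
CKDEPI_CR_2009,female,50,53.04,0.7,false,106.2807986366
CKDEPI_CYS_2012,female,50,53.04,0.7,false,108.4357421151
CKDEPI_CRCYS_2012,female,50,53.04,0.7,false,111.2144879891
CKDEPI_CR_2021,female,50,53.04,0.7,false,109.2830113378
CKDEPI_CRCYS_2021,female,50,53.04,0.7,false,115.4781469776
EKFC_CR,female,50,53.04,0.7,false,102.0421169887
EKFC_CYS,female,50,53.04,0.7,false,102.5116549427
EKFC_CRCYS,female,50,53.04,0.7,false,102.2768859657
CKDEPI_CR_2009,female,80,221.0,2.2,false,17.5598511495
CKDEPI_CYS_2012,female,80,221.0,2.2,false,23.4736599988
CKDEPI_CRCYS_2012,female,80,221.0,2.2,false,19.8554821153
CKDEPI_CR_2021,female,80,221.0,2.2,false,18.9660935010
CKDEPI_CRCYS_2021,female,80,221.0,2.2,false,21.6594984961
EKFC_CR,female,80,221.0,2.2,false,17.0271846045
EKFC_CYS,female,80,221.0,2.2,false,28.7377623398
EKFC_CRCYS,female,80,221.0,2.2,false,22.8824734722
CKDEPI_CR_2009,male,50,123.76,1.5,true,67.4179235348
CKDEPI_CRCYS_2012,female,50,53.04,0.7,true,120.1116470282
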