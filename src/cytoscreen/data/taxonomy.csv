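index,code,category,tbs_targets,detection_class,definition
1,AGC_A,glandular-intraepithelial,AGC_NOS;AGC_FN;AIS;ADC,1,"Atypical glandular cells, pathological morphology similar to cervical gland cells"
2,AGC_B,glandular-intraepithelial,AGC_NOS;AGC_FN;AIS;ADC,1,"Atypical glandular cells, other pathological morphology"
3,ASC_L_S,squamous-intraepithelial,ASCUS;LSIL;ASCH;HSIL;SCC,2,"Single atypical squamous cell with low nuclear/cytoplasmic ratio (excluding koilocytes)"
4,KC,squamous-intraepithelial,LSIL,3,"Single koilocyte"
5,ASC_L_F,squamous-intraepithelial,ASCUS;LSIL;ASCH;HSIL;SCC,3,"Atypical squamous cells with low nuclear/cytoplasmic ratio, arranged in sheets or clusters"
6,ASC_H_B,squamous-intraepithelial,ASCUS;ASCH;HSIL;SCC,4,"Atypical squamous cells with high nuclear/cytoplasmic ratio, arranged in clusters (cell number >= 10)"
7,ASC_H_M,squamous-intraepithelial,ASCUS;ASCH;HSIL;SCC,4,"Atypical squamous cells with high nuclear/cytoplasmic ratio, arranged in clusters (2 <= cell number <= 10)"
8,ASC_H_S,squamous-intraepithelial,ASCUS;ASCH;HSIL;SCC,4,"Single atypical squamous cell with high nuclear/cytoplasmic ratio"
9,SCC_R,squamous-intraepithelial,SCC,4,"Keratinizing squamous cell carcinoma cells"
10,SCC_G,squamous-intraepithelial,SCC,4,"Non-keratinizing squamous carcinoma cells"
11,MC,normal,NILM,excluded,"Superficial squamous epithelium"
12,SC,normal,NILM,5,"Single normal cell with high nuclear/cytoplasmic ratio (parabasal cells, lymphocytes, reserve cells etc.)"
13,RC,normal,NILM,excluded,"Repair and metaplasia cells"
14,GEC,normal,NILM,excluded,"Glandular epithelial cells of cervical tube"
15,EMC,EMC,EMC,6,"Endometrial cells"
16,TRI,infectious,TRI,7,"Trichomonas vaginalis"
17,CAN,infectious,CAN,8,"Candida albicans"
18,HSV,infectious,HSV,9,"Herpes simplex virus"
19,ACTINO,infectious,ACTINO,10,"Actinomycetes"
20,CC,infectious,CC,11,"Clue cells"
21,PH,evidence-of-infection,NILM,12,"Perinuclear halo"
22,Neutrophils,normal,NILM,excluded,"Neutrophils"
23,Mucus,normal,NILM,excluded,"Mucus"
24,Debris,normal,NILM,excluded,"Debris"
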