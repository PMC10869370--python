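person_id,sex,genotype_brca1,genotype_rnf43,age_last_contact,event_type,age,tumor_type,location,histology,size_min_mm,size_max_mm,count,background_lesion
001,F,carrier,carrier,67,cancer,53,CRC,Caecum,Adenocarcinoma,,,,
001,F,carrier,carrier,67,cancer,62,Peritoneal,,,,,,
001,F,carrier,carrier,67,cancer,63,Ovarian,,,,,,
001,F,carrier,carrier,67,polyp,57,,Colon,hyperplastic,,,1,false
002,F,unknown,unknown,,cancer,58,CRC,Colon,Adenocarcinoma,,,,
005,F,unknown,unknown,,cancer,67,Intestinal,,,,,,
006,M,unknown,unknown,,cancer,80,Laryngeal,Larynx,,,,,
009,F,carrier,carrier,,cancer,44,CRC,Transverse colon,Adenocarcinoma,,,,
010,F,carrier,carrier,63,polyp,44,,Ascending colon,tubular_adenoma,,,1,false
010,F,carrier,carrier,63,cancer,56,CRC,Sigmoid colon,Adenocarcinoma,,,,
010,F,carrier,carrier,63,polyp,56,,Sigmoid colon,SSL,15,15,1,true
010,F,carrier,carrier,63,polyp,56,,Transverse colon,hyperplastic,10,10,1,false
010,F,carrier,carrier,63,polyp,59,,Ascending colon,adenomatous,6,8,1,false
010,F,carrier,carrier,63,polyp,59,,Ascending colon,SSL,6,8,1,false
010,F,carrier,carrier,63,polyp,59,,Sigmoid colon,hyperplastic,6,8,2,false
010,F,carrier,carrier,63,polyp,62,,Rectum,hyperplastic,5,8,1,false
011,F,wildtype,wildtype,61,none,,,,,,,,
012,M,wildtype,wildtype,60,none,,,,,,,,
013,F,unknown,unknown,,cancer,,Uterine,,,,,,
014,M,carrier,carrier,,cancer,56,CRC,Transverse colon,Adenocarcinoma,,,,
014,M,carrier,carrier,,cancer,71,Prostate,Prostate,,,,,
016,M,wildtype,wildtype,,cancer,46,Lymphoma,Right neck lymph node,Follicular lymphoma,,,,
017,F,wildtype,wildtype,50,none,,,,,,,,
018,M,carrier,wildtype,,cancer,57,Laryngeal,Larynx,Squamous cell carcinoma,,,,
018,M,carrier,wildtype,,cancer,58,Prostate,Prostate (Right lobe),Adenocarcinoma,,,,
021,F,wildtype,wildtype,,cancer,34,Cervical,Uterus cervix,,,,,
023,M,wildtype,wildtype,54,none,,,,,,,,
024,F,wildtype,wildtype,84,none,,,,,,,,
025,F,obligate_carrier,obligate_carrier,,cancer,34,Breast,,,,,,
026,M,carrier,carrier,58,none,,,,,,,,
027,M,carrier,carrier,,cancer,57,Metastatic cancer of unknown primary,Liver,,,,,
028,F,wildtype,carrier,54,none,,,,,,,,
030,M,wildtype,wildtype,82,none,,,,,,,,
034,F,unknown,unknown,,cancer,,Intestinal,,,,,,
036,F,wildtype,wildtype,,cancer,50,Endometrial,Uterus,Adenocarcinoma,,,,
042,F,wildtype,wildtype,44,none,,,,,,,,
045,M,unknown,unknown,,cancer,,Lung,,,,,,
047,F,unknown,unknown,,cancer,,Kidney,,,,,,
055,M,wildtype,not_tested,35,none,,,,,,,,
056,F,carrier,not_tested,,cancer,,Breast,,,,,,
100,F,carrier,not_tested,28,none,,,,,,,,
101,F,wildtype,not_tested,26,none,,,,,,,,
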