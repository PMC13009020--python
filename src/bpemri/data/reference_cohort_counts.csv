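block,category,grade1,grade2,grade3,grade4
cohort,n,471,299,205,99
race_ethnicity,White,335,204,153,67
race_ethnicity,Black or African American,94,63,34,22
race_ethnicity,Asian,10,8,4,2
race_ethnicity,Hispanic or Latino,14,14,6,7
race_ethnicity,American Indian or Alaska Native,13,4,5,1
race_ethnicity,Native Hawaiian or Pacific Islander,1,2,1,0
race_ethnicity,Multi-racial,4,4,1,0
molecular_subtype,HR+HER2-,296,173,121,58
molecular_subtype,HR+HER2+,54,37,20,12
molecular_subtype,HR-HER2+,29,24,19,3
molecular_subtype,Triple negative,92,65,45,26
menopausal_status,Premenopausal,157,149,120,72
menopausal_status,Postmenopausal,304,138,76,23
menopausal_status,Unknown,10,12,9,4
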