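code,coding_system,description,category
9S1..,read,White British (synthetic example entry),White
9S10.,read,White Irish (synthetic example entry),White
9S17.,read,Other White background (synthetic example entry),White
9S6..,read,Indian (synthetic example entry),Asian
9S7..,read,Pakistani (synthetic example entry),Asian
9S8..,read,Bangladeshi (synthetic example entry),Asian
9S9..,read,Chinese (synthetic example entry),Asian
9S2..,read,Black Caribbean (synthetic example entry),Black
9S3..,read,Black African (synthetic example entry),Black
9S4..,read,Other Black background (synthetic example entry),Black
9SB1.,read,Mixed White and Black Caribbean (synthetic example entry),Mixed/Multiple
9SB2.,read,Mixed White and Asian (synthetic example entry),Mixed/Multiple
9SB4.,read,Other Mixed background (synthetic example entry),Mixed/Multiple
9SE..,read,Other ethnic group (synthetic example entry),Other
9SZ..,read,Ethnicity not stated (synthetic example entry),Unknown
9t0..,read,Ethnicity unknown (synthetic example entry),Unknown
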