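code,coding_system,description,category
494131000000105,snomed,White British (synthetic example entry),White
494161000000100,snomed,White Irish (synthetic example entry),White
494191000000106,snomed,Other White background (synthetic example entry),White
494351000000102,snomed,Indian (synthetic example entry),Asian
494381000000108,snomed,Pakistani (synthetic example entry),Asian
494411000000105,snomed,Bangladeshi (synthetic example entry),Asian
494441000000106,snomed,Chinese (synthetic example entry),Asian
494471000000100,snomed,Black Caribbean (synthetic example entry),Black
494501000000107,snomed,Black African (synthetic example entry),Black
494531000000101,snomed,Other Black background (synthetic example entry),Black
494251000000104,snomed,Mixed White and Black Caribbean (synthetic example entry),Mixed/Multiple
494281000000105,snomed,Mixed White and Asian (synthetic example entry),Mixed/Multiple
494311000000101,snomed,Other Mixed background (synthetic example entry),Mixed/Multiple
494561000000106,snomed,Other ethnic group (synthetic example entry),Other
494591000000100,snomed,Ethnicity not stated (synthetic example entry),Unknown
494621000000102,snomed,Ethnicity unknown (synthetic example entry),Unknown
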