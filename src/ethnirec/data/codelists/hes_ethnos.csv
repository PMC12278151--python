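code,coding_system,description,category
A,hes_ethnos,White - British,White
B,hes_ethnos,White - Irish,White
C,hes_ethnos,White - Any other White background,White
D,hes_ethnos,Mixed - White and Black Caribbean,Mixed/Multiple
E,hes_ethnos,Mixed - White and Black African,Mixed/Multiple
F,hes_ethnos,Mixed - White and Asian,Mixed/Multiple
G,hes_ethnos,Mixed - Any other Mixed background,Mixed/Multiple
H,hes_ethnos,Asian or Asian British - Indian,Asian
J,hes_ethnos,Asian or Asian British - Pakistani,Asian
K,hes_ethnos,Asian or Asian British - Bangladeshi,Asian
L,hes_ethnos,Asian - Any other Asian background,Asian
R,hes_ethnos,Chinese,Asian
M,hes_ethnos,Black or Black British - Caribbean,Black
N,hes_ethnos,Black or Black British - African,Black
P,hes_ethnos,Black - Any other Black background,Black
S,hes_ethnos,Any other ethnic group,Other
Z,hes_ethnos,Not stated,Unknown
99,hes_ethnos,Not known,Unknown
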