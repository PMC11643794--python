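fatty_acid,class,percent
"Myristic, C14:0",SFA,0.03
"Pentadecanoic, C15:0",SFA,0.01
"Palmitic, C16:0",SFA,6.50
"Palmitoleic, C16:1 c9",MUFA,0.10
"Eptadecanoic, C17:0",SFA,0.04
"Eptadecenoic, C17:1 c9",MUFA,0.02
"Stearic, C18:0",SFA,2.77
"Oleic, C18:1 c9",MUFA,13.12
"Octadecenoic, C18:1 c11",MUFA,1.02
"Linoleic, C18:2 n-6",PUFA,56.77
"Arachidic, C20:0",SFA,0.68
"gamma-Linolenic, C18:3 n-6",PUFA,1.83
"alpha-Linolenic, C18:3 n-3",PUFA,16.19
"Stearidonic, C18:4 n-3",PUFA,0.47
"Eicosadienoic, C20:2 n-6",PUFA,0.05
"Behenic, C22:0",SFA,0.29
"Lignoceric, C24:0",SFA,0.12
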