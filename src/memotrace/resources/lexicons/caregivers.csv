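surface,canonical
husband,husband
hubby,husband
wife,wife
daughter,daughter
dtr,daughter
dghtr,daughter
son,son
son in law,son_in_law
daughter in law,daughter_in_law
dil,daughter_in_law
grandson,grandson
granddaughter,granddaughter
gdtr,granddaughter
nephew,nephew
niece,niece
cousin,cousin
brother,brother
bro,brother
sister,sister
sis,sister
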