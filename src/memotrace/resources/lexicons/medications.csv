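surface,canonical
donepezil,donepezil
aricept,donepezil
memantine,memantine
namenda,memantine
rivastigmine,rivastigmine
exelon,rivastigmine
galantamine,galantamine
razadyne,galantamine
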