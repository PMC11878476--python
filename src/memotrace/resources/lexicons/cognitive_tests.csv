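surface,canonical
mmse,mmse
mini mental state examination,mmse
slums,slums
saint louis university mental status,slums
moca,moca
montreal cognitive assessment,moca
mini cog,mini_cog
clock drawing,clock_drawing
clock drawing test,clock_drawing
trail making,trail_making
trail making test,trail_making
boston naming,boston_naming
boston naming test,boston_naming
wisconsin card sorting,wisconsin_card_sorting
wisconsin card sorting test,wisconsin_card_sorting
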