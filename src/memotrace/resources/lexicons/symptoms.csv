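surface,canonical
memory loss,memory_loss
loss of memory,memory_loss
memory deficit,memory_loss
memory problems,memory_loss
memory problem,memory_loss
memory issues,memory_loss
memory impairment,memory_loss
memory lapses,memory_loss
worsening memory,memory_loss
poor memory,memory_loss
trouble remembering,memory_loss
difficulty remembering,memory_loss
not recalling,memory_loss
poor recall,memory_loss
blackout,memory_loss
blackouts,memory_loss
forgetfulness,forgetfulness
forgetful,forgetfulness
forgetting,forgetfulness
forgetting things,forgetfulness
forgets names,forgetfulness
short term memory,short_term_memory_deficit
short term memory loss,short_term_memory_deficit
short term memory deficit,short_term_memory_deficit
poor short term memory,short_term_memory_deficit
stm deficit,short_term_memory_deficit
confusion,confusion
confused,confusion
episodes of confusion,confusion
increasing confusion,confusion
cognitive impairment,cognitive_impairment
cognition impairment,cognitive_impairment
cognitive decline,cognitive_impairment
cognitive deficit,cognitive_impairment
declining cognition,cognitive_impairment
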