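# lac operon model parameters (nM, minutes)
growth_rate = 0.011552453009332421      # ln(2)/60, 60-min generation time
permease_import_turnover = 2400.0
bgal_lactose_turnover = 600.0
lactose_to_allolactose_branching = 0.448
bgal_allolactose_turnover = 25.0
basal_bgal_level = 34.2
induced_bgal_level = 34286.0
external_lactose = 11700.0
permease_Km = 500000.0
bgal_lactose_Km = 2530.0
bgal_allolactose_Km = 1200.0
half_max_induction = 1000.0
mrna_transcription_rate = 20.0
mrna_degradation_rate = 0.6666666666666666
hill_number = 2.0
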