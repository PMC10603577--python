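group,measure,criterion,value
overall,n_total,,105261
african_american,n_total,,19258
japanese_american,n_total,,27227
latino,n_total,,21383
nhpi,n_total,,8368
white,n_total,,29025
overall,incident_cases_6yr,,1464
african_american,incident_cases_6yr,,432
japanese_american,incident_cases_6yr,,315
latino,incident_cases_6yr,,159
nhpi,incident_cases_6yr,,125
white,incident_cases_6yr,,433
overall,eligible,uspstf_2021,25282
african_american,eligible,uspstf_2021,4115
japanese_american,eligible,uspstf_2021,6932
latino,eligible,uspstf_2021,3360
nhpi,eligible,uspstf_2021,2104
white,eligible,uspstf_2021,8771
overall,eligible,uspstf_2013,15681
african_american,eligible,uspstf_2013,2486
japanese_american,eligible,uspstf_2013,4301
latino,eligible,uspstf_2013,2110
nhpi,eligible,uspstf_2013,1137
white,eligible,uspstf_2013,5647
overall,eligible,plco_update_risk_1.3pct,25284
african_american,eligible,plco_update_risk_1.3pct,6879
japanese_american,eligible,plco_update_risk_1.3pct,5837
latino,eligible,plco_update_risk_1.3pct,2549
nhpi,eligible,plco_update_risk_1.3pct,2071
white,eligible,plco_update_risk_1.3pct,7948
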