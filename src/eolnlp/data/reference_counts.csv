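cluster,label,n_patients,n_deaths_7d
ceiling_of_care,treatment escalation plan,3181,55
ceiling_of_care,not for inotropes,20,
ceiling_of_care,not for hdu,39,
ceiling_of_care,currently for full,83,17
ceiling_of_care,ceiling of rx / ceiling of care / ceilings of care / ceilings of treatment / ceiling of treatment,1254,203
ceiling_of_care,ceiling of care / ceilings of care / limit of care / limits of care,910,169
ceiling_of_care,ceilings of treatment / ceiling of rx,431,54
ceiling_of_care,not for intubation / not suitable for intubation / not appropriate for intubation,184,51
ceiling_of_care,not for itu / not for icu / not suitable for itu / not appropriate for itu / not for escalation to itu / not for critical care,284,99
ceiling_of_care,ward based ceiling of care / ward based care only,140,53
ceiling_of_care,not for escalation / escalation beyond,193,75
ceiling_of_care,unsurvivable,59,34
end_of_life,palliative treatments only / palliative input / palliative medications / palliation,1165,390
end_of_life,withdrawal of care / withdrawal of treatment / withdrawal of intensive,67,38
end_of_life,terminal care / end of life care / eol care / eolc,2138,1230
control,none of the above phrases,424905,3406
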