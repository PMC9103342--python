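respondent,round,question,code,dpsir_tag,vote
r01,1,source,intrafamily,,
r02,1,source,intrafamily,,
r03,1,source,intrafamily,,
r04,1,source,intrafamily,,
r05,1,source,intrafamily,,
r06,1,source,intrafamily,,
r07,1,source,intrafamily,,
r08,1,source,intrafamily,,
r09,1,source,intrafamily,,
r10,1,source,intrafamily,,
r11,1,source,intrafamily,,
r12,1,source,intrafamily,,
r13,1,source,intrafamily,,
r01,1,referral,guardianship_council,,
r02,1,referral,guardianship_council,,
r03,1,referral,guardianship_council,,
r04,1,referral,guardianship_council,,
r05,1,referral,guardianship_council,,
r06,1,referral,guardianship_council,,
r07,1,referral,guardianship_council,,
r08,1,referral,psychological_support,,
r09,1,referral,psychological_support,,
r10,1,referral,psychological_support,,
r11,1,referral,psychological_support,,
r12,1,referral,psychological_support,,
r13,1,referral,psychological_support,,
r01,1,referral,institutional_care,,
r02,1,referral,institutional_care,,
r03,1,referral,institutional_care,,
r04,1,referral,institutional_care,,
r05,1,referral,institutional_care,,
r06,1,referral,medium_complexity_social_protection,,
r07,1,referral,medium_complexity_social_protection,,
r08,1,referral,medium_complexity_social_protection,,
r09,1,referral,medium_complexity_social_protection,,
r10,1,referral,police_report,,
r11,1,referral,police_report,,
r12,1,referral,police_report,,
r13,1,referral,extended_family_host,,
r01,1,referral,extended_family_host,,
r02,1,referral,hospital_care,,
r03,1,referral,hospital_care,,
r04,1,referral,legal_medical_institute,,
r05,1,referral,legal_medical_institute,,
r06,1,referral,prosecution_judiciary_center,,
r07,1,referral,family_custody_removal,,
r01,1,goal,full_protection,,
r02,1,goal,full_protection,,
r03,1,goal,full_protection,,
r04,1,goal,full_protection,,
r05,1,goal,full_protection,,
r06,1,goal,full_protection,,
r07,1,goal,full_protection,,
r08,1,goal,full_protection,,
r09,1,goal,full_protection,,
r10,1,goal,full_protection,,
r11,1,goal,full_protection,,
r12,1,goal,mental_health_preservation,,
r13,1,goal,mental_health_preservation,,
r01,1,goal,mental_health_preservation,,
r02,1,goal,mental_health_preservation,,
r03,1,goal,mental_health_preservation,,
r04,1,goal,family_bonds_strengthening,,
r05,1,goal,family_bonds_strengthening,,
r06,1,goal,family_bonds_strengthening,,
r07,1,goal,sti_prevention_treatment,,
r08,1,goal,sti_prevention_treatment,,
r09,1,goal,legal_protection,,
r10,1,goal,revictimization_prevention,,
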