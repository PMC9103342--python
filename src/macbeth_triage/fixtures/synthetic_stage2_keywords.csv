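respondent,round,question,code,dpsir_tag,vote
r01,1,Q1,poverty,Drivers,
r01,1,Q1,alcohol_and_drug_abuse,Drivers,
r02,1,Q1,household_overcrowding,Drivers,
r03,1,Q1,economic_dependence,Drivers,
r01,1,Q2,death_threat,Pressures,
r02,1,Q2,blackmail,Pressures,
r03,1,Q2,coercion,Pressures,
r04,1,Q2,pact_of_silence,Pressures,
r01,1,Q3,bodily_injury,State,
r02,1,Q3,genital_injury,State,
r03,1,Q3,sti_contamination,State,
r04,1,Q3,pregnancy,State,
r01,1,Q4,fear,State,
r02,1,Q4,isolation,State,
r03,1,Q4,aggressiveness,State,
r01,1,Q5,depression,State,
r02,1,Q5,phobic_anxiety,State,
r03,1,Q5,post_traumatic_stress,State,
r01,1,Q6,family_breakdown,Impact,
r02,1,Q6,school_problems,Impact,
r03,1,Q6,revictimization,Impact,
r04,1,Q6,blackmail,Impact,
r01,1,Q7,protection_network_referral,Response,
r02,1,Q7,psychological_support,Response,
r03,1,Q7,foster_care,Response,
r04,1,Q7,longitudinal_monitoring,Response,
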