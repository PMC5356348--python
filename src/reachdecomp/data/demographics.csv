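group,subject,age_years,gender,mmse,side,stroke_duration_months,fm
stroke,S1,79,M,29,right,143,55
stroke,S2,46,M,28,left,4,58
stroke,S3,55,M,28,right,72,53
stroke,S4,58,M,27,right,69,45
stroke,S5,72,M,26,left,105,52
stroke,S6,81,M,30,left,130,40
stroke,S7,57,M,26,left,70,63
stroke,S8,55,F,30,left,19,45
stroke,S9,67,F,29,right,109,40
stroke,S10,45,M,30,right,12,30
stroke,S11,59,M,29,right,24,53
stroke,S12,71,M,28,right,13,65
stroke,S13,71,M,30,left,118,41
stroke,S14,57,M,30,right,22,51
stroke,S15,73,M,29,left,105,55
stroke,S16,65,M,30,left,100,33
control,C1,47,M,30,right,,
control,C2,53,M,27,right,,
control,C3,44,M,29,right,,
control,C4,69,M,29,right,,
control,C5,49,F,30,right,,
control,C6,53,M,28,right,,
control,C7,62,F,30,right,,
control,C8,55,F,30,right,,
control,C9,70,F,29,right,,
control,C10,63,F,30,right,,
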