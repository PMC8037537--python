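transcript_id	name
ENSCINT00000030078	cin-mir-1473
ENSCINT00000035831	cin-mir-3598
ENSCINT00000033430	cin-mir-4011
ENSCINT00000031162	cin-mir-4012-1
ENSCINT00000034078	cin-mir-4016-1
ENSCINT00000032003	cin-mir-4019
ENSCINT00000035935	cin-mir-4024
ENSCINT00000032443	cin-mir-4030
ENSCINT00000030503	cin-mir-4031
ENSCINT00000030983	cin-mir-4034
ENSCINT00000034251	cin-mir-4049
ENSCINT00000034742	cin-mir-4052
ENSCINT00000033641	cin-mir-4053
ENSCINT00000035897	cin-mir-4056
ENSCINT00000034395	cin-mir-4061
ENSCINT00000030710	cin-mir-4062
ENSCINT00000030744	cin-mir-4066
ENSCINT00000036059	cin-mir-4069
ENSCINT00000034132	cin-mir-4075
ENSCINT00000035254	cin-mir-4079
ENSCINT00000030637	cin-mir-4089
ENSCINT00000030429	cin-mir-4094
ENSCINT00000034249	cin-mir-4098
ENSCINT00000035687	cin-mir-4109
ENSCINT00000032059	cin-mir-4110
ENSCINT00000035827	cin-mir-4127
ENSCINT00000035006	cin-mir-4144
ENSCINT00000034925	cin-mir-4150
ENSCINT00000034736	cin-mir-4158
ENSCINT00000031184	cin-mir-4163
ENSCINT00000035929	cin-mir-4180
ENSCINT00000030226	cin-mir-4183
ENSCINT00000032396	cin-mir-4186
ENSCINT00000034165	cin-mir-4187
ENSCINT00000035972	cin-mir-4189
ENSCINT00000030905	cin-mir-4197
ENSCINT00000032545	cin-mir-4200
ENSCINT00000032095	cin-mir-5596b
ENSCINT00000037127	cin-mir-5598
ENSCINT00000030505	cin-mir-5600
ENSCINT00000031547	cin-mir-5605
ENSCINT00000035882	cin-mir-5609
ENSCINT00000033499	cin-mir-5611
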