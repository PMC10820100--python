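year,births_male,births_female,births_unknown,dead_male,dead_female,dead_unknown,removed_male,removed_female,removed_unknown
2019,198,191,3,36,31,0,5,1,0
2020,238,247,3,98,102,0,8,3,0
2021,111,154,2,58,99,0,1,3,0
2022,96,108,1,57,72,0,3,0,0
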