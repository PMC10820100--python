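year,granulomas,abscesses
2019,0,7
2020,1,17
2021,5,22
2022,11,24
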