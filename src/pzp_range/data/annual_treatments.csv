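year,mature_total,mature_vaccinated,mature_treatments,immature_total,immature_vaccinated,immature_treatments
2019,1528,760,1195,323,5,6
2020,1794,1070,1706,468,48,69
2021,1993,1202,1734,352,64,101
2022,1963,1257,1821,223,33,57
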