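subject,participated_before,HANV,LAPV,HAPV,LANV
1,yes,2,1,,1
2,yes,3,0,,1
3,yes,2,1,,2
4,yes,4,1,,1
5,yes,0,2,,2
total_1_5,,11,5,,7
6,no,0,0,,0
7,no,3,1,,0
8,no,0,1,,2
9,no,2,3,,1
10,no,2,1,,1
total_6_10,,7,6,,4
total_1_10,,18,11,,11
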