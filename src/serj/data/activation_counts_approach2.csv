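subject,participated_before,HANV,LAPV,HAPV,LANV
1,yes,2,3,,2
2,yes,4,1,,1
3,yes,3,3,,2
4,yes,3,1,,2
5,yes,4,3,,0
total_1_5,,16,11,,7
6,no,0,0,,1
7,no,2,2,,0
8,no,3,1,,1
9,no,4,2,,2
10,no,2,2,,2
total_6_10,,11,7,,6
total_1_10,,27,18,,13
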