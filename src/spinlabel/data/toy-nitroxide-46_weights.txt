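0.00880862453933
0.00555470994445
0.0132890885006
0.0263375740266
0.0122180733536
0.0534804519318
0.03111790802
0.0173842864862
0.0275205682361
0.00961403024581
0.0057166000151
0.00603461072329
0.0472618996458
0.0297308562769
0.00514948382981
0.0304999703036
0.00789950501522
0.00794389931955
0.0117244671574
0.0110003738769
0.0324619294313
0.0553311743245
0.0422697733262
0.0429759526174
0.0187816888382
0.0177207796457
0.0110318689883
0.00789542093361
0.0204167435334
0.0439024547542
0.0308042892943
0.0171709913088
0.0472236158576
0.00973953261159
0.0255488267156
0.0127132203807
0.0130998941194
0.00742127769625
0.00637526607076
0.00697641427243
0.0156147207277
0.0184793782417
0.0549506036655
0.00564412708162
0.0252061160455
0.0419569580697
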