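yi,vi,study_id,obs
-0.335366,0.071916,S00,o0
-0.498562,0.04511,S00,o1
0.00904,0.078688,S00,o2
0.019237,0.065789,S00,o3
-0.179964,0.017534,S00,o4
0.083483,0.08805,S01,o5
0.274714,0.070891,S01,o6
0.518973,0.072885,S01,o7
0.65773,0.020249,S01,o8
0.836826,0.046031,S01,o9
0.029219,0.039664,S02,o10
-0.534115,0.084141,S02,o11
-0.724082,0.061509,S02,o12
-0.124833,0.075821,S02,o13
-0.51291,0.045473,S02,o14
0.084389,0.028179,S03,o15
-0.154257,0.054367,S03,o16
0.054628,0.015105,S03,o17
0.447311,0.07621,S03,o18
0.185748,0.060533,S03,o19
0.217497,0.070647,S04,o20
-0.075491,0.038362,S04,o21
-0.424724,0.087656,S04,o22
-0.008184,0.08145,S04,o23
-0.1623,0.072271,S04,o24
0.239994,0.025571,S05,o25
0.007179,0.047338,S05,o26
0.149406,0.013504,S05,o27
0.202543,0.022343,S05,o28
-0.250175,0.064644,S05,o29
-0.093396,0.069581,S06,o30
0.237314,0.087401,S06,o31
0.569196,0.036066,S06,o32
0.190895,0.039637,S06,o33
0.247844,0.047564,S06,o34
0.060203,0.025158,S07,o35
0.207489,0.020394,S07,o36
0.264667,0.048056,S07,o37
0.358266,0.028153,S07,o38
-0.070457,0.063585,S07,o39
0.004077,0.044972,S08,o40
0.232337,0.076614,S08,o41
-0.152125,0.066021,S08,o42
-0.412027,0.034989,S08,o43
-0.273463,0.076581,S08,o44
0.006006,0.074381,S09,o45
0.410682,0.040998,S09,o46
0.083525,0.033066,S09,o47
0.297929,0.0646,S09,o48
0.050787,0.02118,S09,o49
0.281979,0.025993,S10,o50
0.302323,0.010589,S10,o51
0.175809,0.072954,S10,o52
0.762204,0.063188,S10,o53
0.503835,0.066413,S10,o54
0.566511,0.072458,S11,o55
0.384358,0.046713,S11,o56
-0.403059,0.055499,S11,o57
-0.218636,0.021184,S11,o58
0.159349,0.019162,S11,o59
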