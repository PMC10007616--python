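model,sound,subject,mean_hr_bpm,tp,tn,fp,fn,sen,pre,spe,acc
I,S1,1,61.5,353,255,114,16,95.66,75.59,69.11,82.38
I,S1,2,77.5,453,385,80,12,97.42,84.99,82.8,90.11
I,S1,3,76.67,386,322,138,74,83.91,73.66,70.0,76.96
I,S1,4,77.17,376,363,100,87,81.21,78.99,78.4,79.81
I,S1,5,73.33,419,366,74,21,95.23,84.99,83.18,89.2
I,S1,6,70.5,355,300,123,68,83.92,74.27,70.92,77.42
I,S1,7,59.67,342,318,40,16,95.53,89.53,88.83,92.18
I,S1,8,72.33,411,379,55,23,94.7,88.2,87.33,91.01
I,S1,9,68.33,388,315,95,22,94.63,80.33,76.83,85.73
I,S1,10,59.17,343,251,104,12,96.62,76.73,70.7,83.66
I,S1,11,61.17,318,300,67,49,86.65,82.6,81.74,84.2
I,S1,12,67.33,375,362,42,29,92.82,89.93,89.6,91.21
I,S1,13,63.17,355,315,64,24,93.67,84.73,83.11,88.39
I,S1,14,67.0,399,289,113,3,99.25,77.93,71.89,85.57
I,S1,15,73.0,414,367,71,24,94.52,85.36,83.79,89.16
I,S1,16,63.67,355,327,55,27,92.93,86.59,85.6,89.27
I,S1,17,86.67,488,486,34,32,93.85,93.49,93.46,93.65
I,S1,18,76.67,422,438,22,38,91.74,95.05,95.22,93.48
I,S1,19,80.17,413,448,33,68,85.86,92.6,93.14,89.5
I,S1,20,62.33,355,314,60,19,94.92,85.54,83.96,89.44
I,S2,1,61.5,310,268,27,59,84.01,91.99,90.85,87.05
I,S2,2,77.5,226,187,161,239,48.6,58.4,53.74,50.8
I,S2,3,76.67,251,199,111,209,54.57,69.34,64.19,58.44
I,S2,4,77.17,267,243,131,196,57.67,67.09,64.97,60.93
I,S2,5,73.33,386,300,40,54,87.73,90.61,88.24,87.95
I,S2,6,70.5,281,138,58,142,66.43,82.89,70.41,67.69
I,S2,7,59.67,260,111,43,98,72.63,85.81,72.08,72.46
I,S2,8,72.33,226,188,99,208,52.07,69.54,65.51,57.42
I,S2,9,68.33,109,311,58,301,26.59,65.27,84.28,53.92
I,S2,10,59.17,170,297,24,185,47.89,87.63,92.52,69.08
I,S2,11,61.17,252,50,57,115,68.66,81.55,46.73,63.71
I,S2,12,67.33,83,243,95,321,20.54,46.63,71.89,43.94
I,S2,13,63.17,105,211,101,274,27.7,50.97,67.63,45.73
I,S2,14,67.0,194,298,56,208,48.26,77.6,84.18,65.08
I,S2,15,73.0,252,136,94,186,57.53,72.83,59.13,58.08
I,S2,16,63.67,190,241,93,192,49.74,67.14,72.16,60.2
I,S2,17,86.67,424,255,59,96,81.54,87.78,81.21,81.41
I,S2,18,76.67,375,168,43,85,81.52,89.71,79.62,80.92
I,S2,19,80.17,299,213,54,182,62.16,84.7,79.78,68.45
I,S2,20,62.33,124,197,128,250,33.16,49.21,60.62,45.92
II,S1,1,61.5,366,310,59,3,99.19,86.12,84.01,91.6
II,S1,2,77.5,451,427,38,14,96.99,92.23,91.83,94.41
II,S1,3,76.67,434,403,57,26,94.35,88.39,87.61,90.98
II,S1,4,77.17,424,420,43,39,91.58,90.79,90.71,91.14
II,S1,5,73.33,431,412,28,9,97.95,93.9,93.64,95.8
II,S1,6,70.5,411,368,55,12,97.16,88.2,87.0,92.08
II,S1,7,59.67,350,332,26,8,97.77,93.09,92.74,95.25
II,S1,8,72.33,422,401,33,12,97.24,92.75,92.4,94.82
II,S1,9,68.33,404,367,43,6,98.54,90.38,89.51,94.02
II,S1,10,59.17,351,317,38,4,98.87,90.23,89.3,94.08
II,S1,11,61.17,363,340,27,4,98.91,93.08,92.64,95.78
II,S1,12,67.33,388,386,18,16,96.04,95.57,95.54,95.79
II,S1,13,63.17,371,346,33,8,97.89,91.83,91.29,94.59
II,S1,14,67.0,400,359,43,2,99.5,90.29,89.3,94.4
II,S1,15,73.0,434,400,38,4,99.09,91.95,91.32,95.21
II,S1,16,63.67,377,357,25,5,98.69,93.78,93.46,96.07
II,S1,17,86.67,500,507,13,20,96.15,97.47,97.5,96.83
II,S1,18,76.67,438,449,11,22,95.22,97.55,97.61,96.41
II,S1,19,80.17,464,464,17,17,96.47,96.47,96.47,96.47
II,S1,20,62.33,366,348,26,8,97.86,93.37,93.05,95.45
II,S2,1,61.5,333,268,11,36,90.24,96.8,96.06,92.75
II,S2,2,77.5,400,187,26,65,86.02,93.9,87.79,86.58
II,S2,3,76.67,388,199,43,72,84.35,90.02,82.23,83.62
II,S2,4,77.17,300,243,86,163,64.79,77.72,73.86,68.56
II,S2,5,73.33,411,300,11,29,93.41,97.39,96.46,94.67
II,S2,6,70.5,355,138,36,68,83.92,90.79,79.31,82.58
II,S2,7,59.67,311,111,16,47,86.87,95.11,87.4,87.01
II,S2,8,72.33,343,188,34,91,79.03,90.98,84.68,80.95
II,S2,9,68.33,352,311,24,58,85.85,93.62,92.84,88.99
II,S2,10,59.17,264,297,24,91,74.37,91.67,92.52,82.99
II,S2,11,61.17,311,50,16,56,84.74,95.11,75.76,83.37
II,S2,12,67.33,274,243,55,130,67.82,83.28,81.54,73.65
II,S2,13,63.17,255,211,60,124,67.28,80.95,77.86,71.69
II,S2,14,67.0,294,298,56,108,73.13,84.0,84.18,78.31
II,S2,15,73.0,294,136,88,144,67.12,76.96,60.71,64.95
II,S2,16,63.67,264,241,78,118,69.11,77.19,75.55,72.04
II,S2,17,86.67,434,255,54,86,83.46,88.93,82.52,83.11
II,S2,18,76.67,399,168,23,61,86.74,94.55,87.96,87.1
II,S2,19,80.17,344,213,54,137,71.52,86.43,79.78,74.47
II,S2,20,62.33,254,197,34,120,67.91,88.19,85.28,74.55
III,S1,1,61.5,359,349,20,10,97.29,94.72,94.58,95.93
III,S1,2,77.5,457,464,1,8,98.28,99.78,99.78,99.03
III,S1,3,76.67,439,427,33,21,95.43,93.01,92.83,94.13
III,S1,4,77.17,433,425,38,30,93.52,91.93,91.79,92.66
III,S1,5,73.33,413,422,18,27,93.86,95.82,95.91,94.89
III,S1,6,70.5,423,386,37,0,100.0,91.96,91.25,95.63
III,S1,7,59.67,323,336,22,35,90.22,93.62,93.85,92.04
III,S1,8,72.33,433,403,31,1,99.77,93.32,92.86,96.31
III,S1,9,68.33,384,370,40,26,93.66,90.57,90.24,91.95
III,S1,10,59.17,336,319,36,19,94.65,90.32,89.86,92.25
III,S1,11,61.17,361,347,20,6,98.37,94.75,94.55,96.46
III,S1,12,67.33,401,388,16,3,99.26,96.16,96.04,97.65
III,S1,13,63.17,362,342,37,17,95.51,90.73,90.24,92.88
III,S1,14,67.0,401,360,42,1,99.75,90.52,89.55,94.65
III,S1,15,73.0,432,419,19,6,98.63,95.79,95.66,97.15
III,S1,16,63.67,376,360,22,6,98.43,94.47,94.24,96.34
III,S1,17,86.67,506,511,9,14,97.31,98.25,98.27,97.79
III,S1,18,76.67,434,446,14,26,94.35,96.88,96.96,95.65
III,S1,19,80.17,478,463,18,3,99.38,96.37,96.26,97.82
III,S1,20,62.33,374,349,25,0,100.0,93.73,93.32,96.66
III,S2,1,61.5,365,268,22,4,98.92,94.32,92.41,96.05
III,S2,2,77.5,445,187,27,20,95.7,94.28,87.38,93.08
III,S2,3,76.67,446,199,43,14,96.96,91.21,82.23,91.88
III,S2,4,77.17,457,243,37,6,98.7,92.51,86.79,94.21
III,S2,5,73.33,411,300,22,29,93.41,94.92,93.17,93.31
III,S2,6,70.5,365,138,15,58,86.29,96.05,90.2,87.33
III,S2,7,59.67,345,111,21,13,96.37,94.26,84.09,93.06
III,S2,8,72.33,346,188,30,88,79.72,92.02,86.24,81.9
III,S2,9,68.33,369,311,24,41,90.0,93.89,92.84,91.28
III,S2,10,59.17,305,297,18,50,85.92,94.43,94.29,89.85
III,S2,11,61.17,366,50,12,1,99.73,96.83,80.65,96.97
III,S2,12,67.33,374,243,18,30,92.57,95.41,93.1,92.78
III,S2,13,63.17,355,211,13,24,93.67,96.47,94.2,93.86
III,S2,14,67.0,365,298,23,37,90.8,94.07,92.83,91.7
III,S2,15,73.0,394,136,18,44,89.95,95.63,88.31,89.53
III,S2,16,63.67,351,241,9,31,91.88,97.5,96.4,93.67
III,S2,17,86.67,519,255,12,1,99.81,97.74,95.51,98.35
III,S2,18,76.67,423,168,13,37,91.96,97.02,92.82,92.2
III,S2,19,80.17,432,213,9,49,89.81,97.96,95.95,91.75
III,S2,20,62.33,372,197,16,2,99.47,95.88,92.49,96.93
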