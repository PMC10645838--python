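Name: 2,5-di-O-acetyl-(2-deuterio)-1,3,4,6-tetra-O-methyl-d-mannitol
PeakNumber: 1
RT: 33.5
LinkageClass: t-Fruf
Num Peaks: 10
129 100
162 47.6
161 30.4
87 23.6
101 13.6
102 12.5
75 10.5
145 8.7
72 7.5
146 7.8

Name: 2,5-di-O-acetyl-(2-deuterio)-1,3,4,6-tetra-O-methyl-d-glucitol
PeakNumber: 2
RT: 33.8
LinkageClass: t-Fruf
Num Peaks: 10
129 100
162 39.8
161 35.6
87 24.2
101 13.9
102 12.2
75 10.3
72 8.6
146 6.7
145 6.1

Name: 1,5-di-O-acetyl-(1-deuterio)-2,3,4,6-tetra-O-thylglucitol
Comment: derivative name transcribed verbatim from the source table; apparent typo for tetra-O-methylglucitol
PeakNumber: 3
RT: 35.7
LinkageClass: t-Glcp
Num Peaks: 11
102 100
129 70.8
145 55.2
118 53.8
101 51.1
71 34.6
87 35.8
162 33.8
161 31.6
205 19.6
72 1.68

Name: 2,5,6-tri-O-acetyl-(2-deuterio)-1,3,4-tri-O-methylmannitol
PeakNumber: 4
RT: 40.8
LinkageClass: 2-6-Fruf
Num Peaks: 10
129 100
162 41.2
87 32.1
189 16.0
99 13.1
102 11.9
75 8.6
72 6.35
71 3.74
60 2.11

Name: 1,2,5-tri-O-acetyl-(2-deuterio)-3,4,6-tri-O-methylmannitol
PeakNumber: 5
RT: 41.6
LinkageClass: 2-1-Fruf
Num Peaks: 10
129 100
87 30.1
190 23.3
161 22.1
101 10.9
100 10.4
75 6.9
145 6.6
71 6.4
72 5.2

Name: 2,5,6-tri-O-acetyl-(2-deuterio)-1,3,4-tri-O-methylglucitol 1,2,5-tri-O-acetyl-(2-deuterio)-3,4,6-tri-O-methylglucitol
PeakNumber: 6
RT: 41.9
LinkageClass: 2-6/1-Fruf
Num Peaks: 12
129 100
87 30.1
161 22.3
190 17.3
162 11.0
101 9.6
100 8.2
189 6.7
71 6.1
75 6.6
72 5.25
118 1.4

Name: 1,5,6-tri-O-acetyl-(1-deuterio)-2,3,4-tri-O-methylglucitol
PeakNumber: 7
RT: 44.1
LinkageClass: i-Glcp
Num Peaks: 10
102 100
118 69.5
129 68.4
87 48.4
101 28.4
162 25.6
189 20.0
71 14.8
233 7.9
145 0.80

Name: 1,2,5,6-tetra-O-acetyl-(2-deuterio)-3,4-di-O-methylhexitol
PeakNumber: 8
RT: 52.9
LinkageClass: 1,6-di-Fruf
Num Peaks: 9
129 100
87 36.7
190 24.2
189 16.2
99 11.6
100 11.1
72 3.8
71 3.3
60 1.5
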