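# Wedge-model dinucleotide step angles, degrees.
# roll/tilt are the components of the wedge deflection (roll = wedge*cos(dir),
# tilt = wedge*sin(dir)); twist is the helical rotation per step. Transcribed
# from the classic trinucleotide-calibrated wedge parameter set of the DNA
# curvature literature; version 1. Complementary steps carry equal roll and
# twist and opposite tilt, which makes the model strand-symmetric.
dinucleotide	twist	wedge	direction
AA	35.62	7.2	-154
AC	34.40	1.1	143
AG	27.70	8.4	2
AT	31.50	2.6	0
CA	34.50	3.5	-64
CC	33.67	2.1	-57
CG	29.80	6.7	0
CT	27.70	8.4	-2
GA	36.90	5.3	120
GC	40.00	5.0	180
GG	33.67	2.1	57
GT	34.40	1.1	-143
TA	36.00	0.9	0
TC	36.90	5.3	-120
TG	34.50	3.5	64
TT	35.62	7.2	154
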