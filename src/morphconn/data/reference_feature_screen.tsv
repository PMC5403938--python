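feature	icc	p
NumVert	0.95	0.00031
SurfArea	0.99	7.3e-06
GrayVol	0.96	0.00016
ThickAvg	0.73	0.053
ThickStd	0.94	0.00063
MeanCurv	0.8	0.024
GausCurv	0.68	0.076
FoldInd	0.73	0.76
CurvInd	0.36	0.29
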