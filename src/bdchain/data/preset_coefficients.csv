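model,symbol,kind,midline,amplitude
model33,r1,sine,5.5,0.5
model33,a11,sine,1.2,1.0
model33,a12,sine,0.062,0.0005
model33,beta1,sine,0.5,0.1
model33,gamma1,sine,0.11,0.01
model33,sigma1,sine,0.5,0.1
model33,r2,cosine,0.005,0.001
model33,a21,sine,5.5,0.5
model33,a22,cosine,2.75,0.25
model33,a23,sine,0.03,0.004
model33,beta2,sine,1.5,0.2
model33,gamma2,sine,0.11,0.01
model33,sigma2,sine,0.2,0.1
model33,r3,sine,0.002,0.001
model33,a32,sine,10.0,0.5
model33,a33,cosine,4.25,0.2
model33,sigma3,sine,0.15,0.075
model35,r1,sine,5.5,0.5
model35,a11,sine,1.2,1.0
model35,a12,sine,0.062,0.0005
model35,beta1,sine,0.5,0.1
model35,gamma1,sine,0.11,0.01
model35,sigma1,sine,0.5,0.1
model35,r2,cosine,0.005,0.001
model35,a21,sine,5.5,0.5
model35,a22,cosine,2.75,0.25
model35,a23,sine,0.03,0.004
model35,beta2,sine,1.5,0.2
model35,gamma2,sine,0.11,0.01
model35,sigma2,sine,0.2,0.1
model35,r3,sine,0.002,0.001
model35,a32,sine,0.001,0.0005
model35,a33,cosine,4.25,0.2
model35,sigma3,sine,0.15,0.075
model36,r1,sine,3.5,1.5
model36,a11,sine,1.5,1.0
model36,a12,sine,0.15,0.1
model36,beta1,sine,2.0,0.5
model36,gamma1,sine,1.2,0.5
model36,sigma1,sine,0.5,0.1
model36,r2,cosine,0.02,0.01
model36,a21,sine,4.0,0.5
model36,a22,cosine,1.5,0.25
model36,a23,sine,0.15,0.1
model36,beta2,sine,0.25,0.1
model36,gamma2,sine,2.5,0.5
model36,sigma2,sine,0.2,0.1
model36,r3,sine,0.0005,0.0001
model36,a32,sine,2.0,0.5
model36,a33,cosine,7.25,0.25
model36,sigma3,sine,0.015,0.0075
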