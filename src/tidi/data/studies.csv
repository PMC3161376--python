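id,label,events_trt,n_trt,events_ctl,n_ctl,y,se,included
S1,Trial 1,17,366,108,781,,,True
S2,Trial 2,64,729,143,873,,,True
S3,Trial 3,11,114,129,998,,,True
S4,Trial 4,23,709,75,777,,,True
S5,Trial 5,25,871,44,576,,,True
S6,Trial 6,34,737,77,681,,,True
S7,Trial 7,33,350,104,539,,,True
S8,Trial 8,7,138,32,305,,,True
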