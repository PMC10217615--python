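label,1998,2008,2018
STRONGLY AGREE,148,285,186
AGREE,429,602,496
NOT AGREE/DISAGREE,278,210,229
DISAGREE,275,196,181
STRONG DISAGREE,72,30,38
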