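# Major observed peaks of the Boc/OtBu (di-tert-butyl carbamate) standard (m/z)
69
70
71
82
83
84
100
111
112
113
129
147
157
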