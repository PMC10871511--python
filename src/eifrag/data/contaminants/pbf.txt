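# Major observed peaks of the Pbf-Cl protecting-group standard (m/z)
91
100
115
119
129
147
173
174
175
176
189
190
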