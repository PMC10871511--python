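# Major observed peaks of the Fmoc-Cl protecting-group standard (m/z)
88
89
139
151
152
163
164
165
166
176
177
178
179
196
258
260
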