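# Major observed peaks of the Trt-Cl protecting-group standard (m/z)
77
78
105
129
154
155
165
166
167
181
182
183
184
243
244
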