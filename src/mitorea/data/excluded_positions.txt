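# Positions of the 16,569-np mitochondrial reference not interrogated by the
# array (16,569 - 25 = 16,544 callable positions).  np 3107 is the reference
# 'N' placeholder; the remaining 24 lie in homopolymeric / hypervariable
# tracts that resequencing arrays tile poorly (CSB poly-C region around
# np 303-316, the 16183-16193 poly-C run, and a few recurrent problem sites).
# One 1-based position per line; this list is a documented surrogate for the
# array's design file and can be replaced via load_reference(excluded=...).
303
309
310
311
312
313
314
315
316
455
463
573
960
965
3106
3107
5895
5899
8276
8285
16183
16184
16189
16193
16519
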