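# minimal default hypervariable-site list; replace with the
# full published hotspot list for real analyses
309
310
456
463
514
515
16182
16183
16189
16193
16519
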