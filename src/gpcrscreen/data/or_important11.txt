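# Orthosteric positions with site-directed mutagenesis support across
# human and mouse olfactory receptors (subset of orthosteric24).
# version: 1
3.33
3.36
3.37
5.43
5.47
6.48
6.51
6.52
6.55
7.41
7.42
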