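# Canonical class A GPCR orthosteric binding-site positions
# (Ballesteros-Weinstein generic numbering), 24 positions.
# version: 1
3.28
3.29
3.32
3.33
3.36
3.37
4.52
5.39
5.40
5.43
5.44
5.47
5.53
6.44
6.48
6.51
6.52
6.55
6.58
7.31
7.34
7.38
7.41
7.42
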