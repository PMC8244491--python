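# sha256 checksums of bundled tables
eisenberg	c08a0c342e713fd6e0417c2f74bf5881730974cc4ab5d1ff9c0704774ec7699f
orthosteric24	b18720b229a0335f10431d6e2dd180fd7e0985ddb080a5a9464389e9febe2d85
or_important11	d8748c6b6cb3546ed0ecdfd295db6e58058a8ddc291d0e1af3696235147bd678
known_or1a2_ligands	92b8c6b4295dec3c2b28766f1ef42eedbe5ed7243498c7adf7f6cfe60a4a0beb
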