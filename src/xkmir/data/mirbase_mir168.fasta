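>mtr-miR168a MIMAT0011089 Medicago truncatula miR168a (miRBase v22)
UUGCUUGGUGCUGGUCGGGAA
>osa-miR168a-5p MIMAT0001045 Oryza sativa miR168a-5p (miRBase v22)
UCGCUUGGUGCAGAUCGGGAC
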