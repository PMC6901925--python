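>mdm-miR164a MIMAT0025907 (miRBase v22)
UGGAGAAGCAGGGCACAUGCC
>mdm-miR164b MIMAT0025908 (miRBase v22)
UGGAGAAGCAGGGCACGUGCA
>mdm-miR164c MIMAT0025909 (miRBase v22)
UGGAGAAGCAGGGCACGUGCA
>mdm-miR164d MIMAT0025910 (miRBase v22)
UGGAGAAGCAGGGCACGUGCA
>mdm-miR164e MIMAT0025911 (miRBase v22)
UGGAGAAGCAGGGCACGUGCA
>mdm-miR164f MIMAT0025912 (miRBase v22)
UGGAGAAGCAGGGCACGUGCA
>mdm-miR166a MIMAT0025913 (miRBase v22)
UCGGACCAGGCUUCAUUCCCC
>mdm-miR166b MIMAT0025914 (miRBase v22)
UCGGACCAGGCUUCAUUCCCC
>mdm-miR166c MIMAT0025915 (miRBase v22)
UCGGACCAGGCUUCAUUCCCC
>mdm-miR166d MIMAT0025916 (miRBase v22)
UCGGACCAGGCUUCAUUCCCC
>mdm-miR166e MIMAT0025917 (miRBase v22)
UCGGACCAGGCUUCAUUCCCC
>mdm-miR166f MIMAT0025918 (miRBase v22)
UCGGACCAGGCUUCAUUCCCC
>mdm-miR166g MIMAT0025919 (miRBase v22)
UCGGACCAGGCUUCAUUCCCC
>mdm-miR166h MIMAT0025920 (miRBase v22)
UCGGACCAGGCUUCAUUCCCC
>mdm-miR166i MIMAT0025921 (miRBase v22)
UCGGACCAGGCUUCAUUCCCC
>mdm-miR166j MIMAT0043545 (miRBase v22)
UCGGACCAGGCUUCAUUCCCC
>mdm-miR390a MIMAT0025969 (miRBase v22)
AAGCUCAGGAGGGAUAGCGCC
>mdm-miR390b MIMAT0025970 (miRBase v22)
AAGCUCAGGAGGGAUAGCGCC
>mdm-miR390c MIMAT0025971 (miRBase v22)
AAGCUCAGGAGGGAUAGCGCC
>mdm-miR390d MIMAT0025972 (miRBase v22)
AAGCUCAGGAGGGAUAGCGCC
>mdm-miR390e MIMAT0025973 (miRBase v22)
AAGCUCAGGAGGGAUAGCGCC
>mdm-miR390f MIMAT0025974 (miRBase v22)
AAGCUCAGGAGGGAUAGCGCC
>mtr-miR164a MIMAT0011059 (miRBase v22)
UGGAGAAGCAGGGCACGUGCA
>mtr-miR164b MIMAT0011098 (miRBase v22)
UGGAGAAGCAGGGCACGUGCA
>mtr-miR164c MIMAT0011102 (miRBase v22)
UGGAGAAGCAGGGCACGUGCA
>mtr-miR164d MIMAT0011103 (miRBase v22)
UGGAGAAGCAGGGCACAUGCU
>mtr-miR166a MIMAT0001642 (miRBase v22)
UCGGACCAGGCUUCAUUCCCC
>mtr-miR166b MIMAT0011061 (miRBase v22)
UCGGACCAGGCUUCAUUCCUA
>mtr-miR166c MIMAT0011067 (miRBase v22)
UCGGACCAGGCUUCAUUCCUC
>mtr-miR166d MIMAT0011068 (miRBase v22)
UCGGGCCAGGCUUCAUCCCCC
>mtr-miR166e-3p MIMAT0011080 (miRBase v22)
UCGGACCAGGCUUCAUUCCCC
>mtr-miR166e-5p MIMAT0026726 (miRBase v22)
GGAAUGUUGGCUGGCUCGAGG
>mtr-miR166f MIMAT0011100 (miRBase v22)
UCGGACCAGGCUUCAUUCCUC
>mtr-miR166g-3p MIMAT0011104 (miRBase v22)
UCGGACCAGGCUUCAUUCCCC
>mtr-miR166g-5p MIMAT0026730 (miRBase v22)
GGAAUGUUGUCUGGCUCGAGG
>mtr-miR390 MIMAT0011072 (miRBase v22)
AAGCUCAGGAGGGAUAGCGCC
>sly-miR164a-3p MIMAT0033974 (miRBase v22)
CAUGUGCCUGUUUUCCCCAUC
>sly-miR164a-5p MIMAT0033973 (miRBase v22)
UGGAGAAGCAGGGCACGUGCA
>sly-miR164b-3p MIMAT0033976 (miRBase v22)
CACGUGUUCUCCUUCUCCAAC
>sly-miR164b-5p MIMAT0033975 (miRBase v22)
UGGAGAAGCAGGGCACGUGCA
>sly-miR166a MIMAT0007915 (miRBase v22)
UCGGACCAGGCUUCAUUCCCC
>sly-miR166b MIMAT0007916 (miRBase v22)
UCGGACCAGGCUUCAUUCCCC
>sly-miR166c-3p MIMAT0035444 (miRBase v22)
UCGGACCAGGCUUCAUUCCUC
>sly-miR166c-5p MIMAT0035443 (miRBase v22)
GGGAUGUUGUCUGGCUCGACA
>sly-miR390a-3p MIMAT0035468 (miRBase v22)
CGCUAUCCAUCCUGAGUUUUA
>sly-miR390a-5p MIMAT0035467 (miRBase v22)
AAGCUCAGGAGGGAUAGCACC
>sly-miR390b-3p MIMAT0035480 (miRBase v22)
CGCUAUCCAUCCUGAGUUUCA
>sly-miR390b-5p MIMAT0035479 (miRBase v22)
AAGCUCAGGAGGGAUAGCGCC
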