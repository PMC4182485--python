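(das-nov,((ech-tel,(lox-afr,pro-cap)),((hom-sap,((mus-mus,ict-tri),och-pri)),(eri-eur,(myo-luc,(can-fam,(equ-cab,(bos-tau,tur-tru))))))));
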