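protein_change,cdna_change,event_type,effect,phenotype,fxi_c,fxi_ag,allele_frequency,n_patients,aggregate,count
Cys46Phe,,point,missense,type_I,,,,,false,1
Cys56Arg,,point,missense,type_I,,,0.0002,36,false,1
Cys56Trp,,point,missense,type_I,,,,,false,1
Cys76Tyr,,point,missense,type_I,,,,,false,1
Cys110Gly,,point,missense,type_I,,,,,false,1
Cys140Tyr,,point,missense,type_I,,,,,false,1
Cys255Tyr,,point,missense,type_I,,,,,false,1
Cys416Tyr,,point,missense,type_I,,,,,false,1
Cys545Tyr,,point,missense,type_I,,,,,false,1
Cys76Arg/Phe,,point,missense,unknown,,,,,false,1
Cys136Arg,,point,missense,unknown,,,,,false,1
Cys200Ser/Tyr,,point,missense,unknown,,,,,false,1
Cys230Arg/Ser,,point,missense,unknown,,,,,false,1
Cys374Arg,,point,missense,unknown,,,,,false,1
Cys500Arg/Trp,,point,missense,unknown,,,,,false,1
Cys581Arg/Phe,,point,missense,unknown,,,,,false,1
Cys599Tyr,,point,missense,unknown,,,,,false,1
Trp246Cys,,point,missense,type_I,,,,,false,1
Arg326Cys,,point,missense,type_I,,,,,false,1
Trp425Cys,,point,missense,type_I,,,,,false,1
Arg443Cys,,point,missense,type_I,,,,,false,1
Tyr445Cys,,point,missense,type_I,,,,,false,1
Trp515Cys,,point,missense,type_I,,,,,false,1
Trp519Cys,,point,missense,type_I,,,,,false,1
Gly596Cys,,point,missense,type_I,,,,,false,1
Arg396Cys,,point,missense,type_II,30,100,,,false,1
Tyr151Cys,,point,missense,unknown,,,,,false,1
Arg162Cys,,point,missense,unknown,,,,,false,1
Arg268Cys,,point,missense,unknown,,,,,false,1
Tyr521Cys,,point,missense,unknown,,,,,false,1
Phe301Leu,,point,missense,unknown,,,0.0003,22,false,1
Val38Ala,,point,missense,type_I,,,,,false,1
Pro41Leu,,point,missense,type_I,,,,,false,1
Thr51Met,,point,missense,type_I,,,,,false,1
Thr51Ala,,point,missense,type_I,,,,,false,1
Thr51Ile,,point,missense,unknown,,,,,false,1
Gly97Arg,,point,missense,type_I,,,,,false,1
Gly97Asp,,point,missense,type_I,,,,,false,1
Gly97Val,,point,missense,unknown,,,,,false,1
Gly368Glu,,point,missense,type_I,8,10,,,false,1
Gly368Arg,,point,missense,type_II,25,90,,,false,1
Glu135*,,point,nonsense,type_I,,,0.0004,61,false,1
Cys136*,,point,nonsense,type_I,,,,,false,1
Cys146*,,point,nonsense,type_I,,,0.0001,22,false,1
Cys327*,,point,nonsense,type_I,,,,,false,1
Cys599*,,point,nonsense,type_II,,,,,false,1
Cys56*,,point,nonsense,unknown,,,,,false,1
Gln106*,,point,nonsense,unknown,,,0.0002,,false,1
Gln281*,,point,nonsense,unknown,,,0.0001,22,false,1
,g.31.5kb_del,deletion,undefined,unknown,,,,,false,1
Ile308Phe/Thr,,polymorphism,missense,polymorphism,,,0.02,,false,1
Cys339Phe,,polymorphism,missense,polymorphism,,,0.015,,false,1
,,point,missense,type_I,,,0.0002,,true,52
,,point,missense,type_II,,,0.0003,,true,6
,,point,missense,unknown,,,,,true,50
,,point,nonsense,type_I,,,,,true,10
,,point,nonsense,type_II,,,,,true,1
,,point,nonsense,unknown,,,0.0001,,true,8
,,point,silent,unknown,,,,,true,2
,,point,undefined,type_I,,,,,true,2
,,point,undefined,type_II,,,,,true,1
,,point,undefined,unknown,,,,,true,14
,,deletion,undefined,type_I,,,,,true,3
,,deletion,undefined,type_II,,,,,true,1
,,deletion,undefined,unknown,,,,,true,14
,,duplication,undefined,type_I,,,,,true,1
,,duplication,undefined,unknown,,,,,true,3
,,insertion,undefined,unknown,,,,,true,4
,,polymorphism,undefined,polymorphism,,,0.05,,true,6
,,polymorphism,undefined,polymorphism,,,0.005,,true,4
,,polymorphism,undefined,polymorphism,,,0.0001,,true,32
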