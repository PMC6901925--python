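{
 "description": "MFEs computed with RNAhybrid 2.1.2 (-s 3utr_human, best hit) for perfect-complement GC-capped duplexes; frozen as an external oracle for the duplex energy model.",
 "cases": [
  {
   "mirna": "GAGCCUGGGCGUACUAGUC",
   "target": "GACUAGUACGCCCAGGCUC",
   "rnahybrid_mfe": -43.6
  },
  {
   "mirna": "GCAAAGAAAUUCGGAAUC",
   "target": "GAUUCCGAAUUUCUUUGC",
   "rnahybrid_mfe": -30.5
  },
  {
   "mirna": "GAAGGUUGCGUUGUCCGGAUC",
   "target": "GAUCCGGACAACGCAACCUUC",
   "rnahybrid_mfe": -44.4
  },
  {
   "mirna": "GCGGUCUACAAGACUAC",
   "target": "GUAGUCUUGUAGACCGC",
   "rnahybrid_mfe": -34.6
  },
  {
   "mirna": "GAUAUGAGAGAACUAAUC",
   "target": "GAUUAGUUCUCUCAUAUC",
   "rnahybrid_mfe": -30.3
  },
  {
   "mirna": "GUCUAGGUCCUGAUC",
   "target": "GAUCAGGACCUAGAC",
   "rnahybrid_mfe": -31.4
  },
  {
   "mirna": "GGGCAGAUUGUGUACGCCAAGGC",
   "target": "GCCUUGGCGUACACAAUCUGCCC",
   "rnahybrid_mfe": -51.6
  },
  {
   "mirna": "GGAAGGUCUGCCACC",
   "target": "GGUGGCAGACCUUCC",
   "rnahybrid_mfe": -35.1
  },
  {
   "mirna": "GUGAACUACACGCC",
   "target": "GGCGUGUAGUUCAC",
   "rnahybrid_mfe": -28.8
  },
  {
   "mirna": "GAGGCCGUAGAAGGUUAGUAACUC",
   "target": "GAGUUACUAACCUUCUACGGCCUC",
   "rnahybrid_mfe": -48.8
  },
  {
   "mirna": "GAUUUCGGCACUGAGUCUCC",
   "target": "GGAGACUCAGUGCCGAAAUC",
   "rnahybrid_mfe": -42.2
  },
  {
   "mirna": "GUGCGCCUCUGGCAUUAGCC",
   "target": "GGCUAAUGCCAGAGGCGCAC",
   "rnahybrid_mfe": -46.4
  },
  {
   "mirna": "GUAACGGCUGAUGACGCCGUC",
   "target": "GACGGCGUCAUCAGCCGUUAC",
   "rnahybrid_mfe": -46.2
  },
  {
   "mirna": "GGGCGCGCCAUUGGUCAACUAC",
   "target": "GUAGUUGACCAAUGGCGCGCCC",
   "rnahybrid_mfe": -49.8
  },
  {
   "mirna": "GUGGACUGGUGCUGAGCAUC",
   "target": "GAUGCUCAGCACCAGUCCAC",
   "rnahybrid_mfe": -45.1
  },
  {
   "mirna": "GCCAUGAAAUAGAGUGUUC",
   "target": "GAACACUCUAUUUCAUGGC",
   "rnahybrid_mfe": -35.0
  },
  {
   "mirna": "GCUGUGUUAUGCUAACC",
   "target": "GGUUAGCAUAACACAGC",
   "rnahybrid_mfe": -32.7
  },
  {
   "mirna": "GUACCCGACUUACCGUUC",
   "target": "GAACGGUAAGUCGGGUAC",
   "rnahybrid_mfe": -37.0
  },
  {
   "mirna": "GCAAGCGGCUACGAGCUC",
   "target": "GAGCUCGUAGCCGCUUGC",
   "rnahybrid_mfe": -41.4
  },
  {
   "mirna": "GGAGUCGUGAGAGC",
   "target": "GCUCUCACGACUCC",
   "rnahybrid_mfe": -31.5
  },
  {
   "mirna": "GCCCAUUGACUAAUGCAAGUCCCC",
   "target": "GGGGACUUGCAUUAGUCAAUGGGC",
   "rnahybrid_mfe": -51.3
  },
  {
   "mirna": "GGUGCUCGCGUCAAUCC",
   "target": "GGAUUGACGCGAGCACC",
   "rnahybrid_mfe": -38.1
  },
  {
   "mirna": "GAUCUCCGGGCAAAACGC",
   "target": "GCGUUUUGCCCGGAGAUC",
   "rnahybrid_mfe": -38.9
  },
  {
   "mirna": "GGUGAGAAGUGAGUGC",
   "target": "GCACUCACUUCUCACC",
   "rnahybrid_mfe": -34.0
  },
  {
   "mirna": "GGAAGUGAGUCCACGUC",
   "target": "GACGUGGACUCACUUCC",
   "rnahybrid_mfe": -36.7
  },
  {
   "mirna": "GUGGCAAGCGCACAACAAACGC",
   "target": "GCGUUUGUUGUGCGCUUGCCAC",
   "rnahybrid_mfe": -46.7
  },
  {
   "mirna": "GGACAACGGGGAGUGGAGC",
   "target": "GCUCCACUCCCCGUUGUCC",
   "rnahybrid_mfe": -45.4
  },
  {
   "mirna": "GGCAGGGUCUGAGCC",
   "target": "GGCUCAGACCCUGCC",
   "rnahybrid_mfe": -37.5
  },
  {
   "mirna": "GCCACUAGUCUAGCCACGCGC",
   "target": "GCGCGUGGCUAGACUAGUGGC",
   "rnahybrid_mfe": -49.2
  },
  {
   "mirna": "GGUGCCUAAUCCAC",
   "target": "GUGGAUUAGGCACC",
   "rnahybrid_mfe": -29.7
  }
 ]
}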