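{
  "Pelagophyceae": "O_Stramenopiles",
  "Dictyochophyceae": "O_Stramenopiles",
  "Chrysophyceae": "O_Stramenopiles",
  "Bolidophyceae": "O_Stramenopiles",
  "Pinguiophyceae": "O_Stramenopiles",
  "Raphidophyceae": "O_Stramenopiles",
  "Cryptophyta": "O_Eukaryota",
  "Euglenozoa": "O_Eukaryota",
  "Cercozoa": "O_Eukaryota",
  "Ciliophora": "O_Eukaryota",
  "Firmicutes": "O_Bacteria",
  "Actinobacteria": "O_Bacteria",
  "Planctomycetes": "O_Bacteria",
  "Verrucomicrobia": "O_Bacteria",
  "Chloroflexi": "O_Bacteria",
  "Nitrospinae": "O_Bacteria"
}
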