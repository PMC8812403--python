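{
  "treated-inactive": {
    "cluster1": ["TLR1", "TLR2", "TLR4", "TLR6", "TLR8", "BCL6", "NR4A1",
                 "NFKBIA", "LAG3", "HAVCR2", "TIGIT", "PDCD1", "CD40"],
    "cluster2": ["TRA", "CD40LG", "CTLA4", "PDCD1LG2", "CD28", "FOXP3"]
  },
  "treated-active": {
    "cluster1": ["CD274", "LAG3", "RELA", "PDCD1", "CD247", "TRA", "CD40LG",
                 "CD28", "GATA3", "CTLA4", "FOXP3", "TBX21", "CCL5", "RORC"],
    "cluster2": ["NFKB1", "HAVCR2", "TIGIT", "NFKBIA", "CD83", "TNF", "NR4A1"]
  }
}
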