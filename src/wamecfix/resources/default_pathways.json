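{
  "ccf": {
    "role": "ccf_marker",
    "genes": ["K01601", "K01602"]
  },
  "rtca": {
    "role": "ncf_pathway",
    "genes": ["K15230", "K15231", "K00169", "K00170", "K00171", "K00172",
              "K00174", "K00175", "K00176", "K00177", "K01902", "K01903",
              "K00239", "K00240", "K00241", "K01676", "K00024", "K00031",
              "K01681", "K01595"]
  },
  "wood_ljungdahl": {
    "role": "ncf_pathway",
    "genes": ["K00198", "K14138", "K00194", "K00197", "K15023", "K01938",
              "K01491", "K00297", "K05299", "K15022", "K00122", "K00196"]
  },
  "hp_bicycle": {
    "role": "ncf_pathway",
    "genes": ["K02160", "K01961", "K01962", "K01963", "K14468", "K14469",
              "K15052", "K05606", "K01847", "K01848", "K01849", "K08691",
              "K14449", "K14470", "K09709"]
  },
  "hp_hb_cycle": {
    "role": "ncf_pathway",
    "genes": ["K01964", "K15037", "K15036", "K15017", "K15039", "K15018",
              "K15019", "K15020", "K15016", "K14534", "K14977", "K15038"]
  },
  "dc_hb_cycle": {
    "role": "ncf_pathway",
    "genes": ["K00169", "K00170", "K00171", "K00172", "K01007", "K01595",
              "K00024", "K01676", "K00239", "K00240", "K00241", "K01902",
              "K01903", "K15016", "K14465", "K14534", "K15038", "K15017"]
  },
  "photosynthesis_core": {
    "role": "photosynthesis_core",
    "genes": ["K01601", "K01602", "K00855", "K01100", "K11532", "K00134",
              "K00927", "K01623", "K01624", "K01803", "K01807", "K01808",
              "K01783", "K00615", "K00026"]
  },
  "endocytosis_core": {
    "role": "endocytosis_core",
    "genes": ["K00889", "K04646", "K11824", "K11825", "K12471", "K12472",
              "K17917", "K07874", "K07889", "K12478"]
  },
  "rhodopsin": {
    "role": "rhodopsin",
    "genes": ["PF01036"]
  }
}
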