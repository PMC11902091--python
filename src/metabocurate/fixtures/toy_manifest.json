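{
  "description": "Planted structure of the miniature pathway library and layered knowledge graph shipped for tests.",
  "gmt_pathways": 3,
  "gmt_members": {"P1": ["C01", "C02", "C03", "C04"], "P2": ["C05", "C06", "C07"], "P3": ["C07", "C08", "C09", "C10"]},
  "graph_layer_counts": {"pathway": 2, "module": 2, "enzyme": 3, "reaction": 4, "compound": 8},
  "graph_n_nodes": 19,
  "graph_n_edges": 16,
  "isolated_nodes": ["C08"]
}
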