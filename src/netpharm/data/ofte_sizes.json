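{
  "tripartite": {"n_ingredients": 44, "n_targets": 191, "n_pathways": 70, "n_nodes": 305, "n_edges": 879, "mean_degree": 5.76},
  "core": {"n_ingredients": 8, "n_targets": 50, "n_pathways": 1, "n_nodes": 59, "n_edges": 150, "mean_degree": 5.08},
  "projection": {"n_nodes": 142, "n_edges": 2102, "mean_degree": 29.61, "average_path_length": 2.59},
  "hub_ingredients": {"eugenol": 106, "geraniol": 96},
  "core_hub_degrees": {"eugenol": 47, "geraniol": 46},
  "funnel": {"identified": 91, "druglike": 79, "with_targets": 44}
}
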