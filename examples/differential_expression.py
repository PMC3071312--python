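"""Microarray preprocessing and moderated-t differential expression.

Generates a spot-level dataset from planted TF activities, runs the full
preprocessing cascade (background adjust, replicate collapse, glog +
quantile normalization, probe selection, gene filter), and tests the
strain-by-treatment interaction with the moderated t.
"""

import numpy as np
import pandas as pd

from evotol import expression, synth

# a small 2x2 design: 2 strains x 2 treatments x 3 biological replicates
tfs = ["FlhDC", "GadE", "MarA", "PhoP"]
Z = synth.sample_connectivity(80, tfs, seed=3, identifiable=True, n_conditions=4)
P = pd.DataFrame([[0.5, 0.5, -0.5, -0.5],   # strain-dependent activity
                  [0.0, 0.0, 0.0, 0.0],
                  [0.2, -0.2, 0.2, -0.2],   # treatment-dependent activity
                  [0.0, 0.0, 0.0, 0.0]],
                 index=tfs, columns=["mut_ctl", "mut_trt", "ref_ctl", "ref_trt"])
cfg = synth.SimConfig(seed=11, noise_sd=0.05, n_bio_replicates=3, n_tech_replicates=4)
spots, truth = synth.gen_expression_dataset(Z, P, cfg, background_sd=0.02)

design = truth["samples"].copy()
design["strain"] = design["condition"].str.split("_").str[0]
design["treated"] = design["condition"].str.endswith("trt")

adjusted = expression.background_adjust(spots)
collapsed = expression.collapse_replicates(adjusted, design)
normalized = expression.normalize(collapsed)
probe_to_gene = pd.Series({p: p.rsplit("_", 1)[0] for p in normalized.index})
genes = expression.select_probe_per_gene(normalized, probe_to_gene, design)
filtered = expression.filter_genes(genes, intensity_min=0.0, iqr_min=0.05)
print(f"{len(genes)} genes after probe selection, {len(filtered)} after filtering")

result = expression.moderated_t_test(filtered, design, "ref_treatment",
                                     fdr_cutoff=0.05)
print(result.sort_values("p").head(8)[["gene", "effect", "t", "p", "p_adj"]]
      .to_string(index=False))
n_sig = int(result["significant"].sum())
print(f"\n{n_sig} genes significant for the treatment effect at FDR 0.05")
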