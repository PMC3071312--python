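"""Infer transcription-factor activities with network component analysis.

First decomposes a small identifiable instance and compares the inferred
activities with the planted truth; then runs the subset-consensus
procedure on a 16-TF instance where only 4 TFs truly differ between
strains and the number of conditions is far too small for one joint
decomposition.
"""

import numpy as np
import pandas as pd

from evotol import nca, synth
from evotol.validation import consensus_case

# --- direct decomposition on an identifiable 4-TF instance -----------------
tfs = ["TF1", "TF2", "TF3", "TF4"]
Z = synth.sample_connectivity(120, tfs, seed=5, identifiable=True, n_conditions=4)
rng = np.random.default_rng(5)
A = np.where(Z.to_numpy() != 0, rng.uniform(0.5, 1.5, Z.shape), 0.0)
P = pd.DataFrame(rng.standard_normal((4, 4)), index=tfs,
                 columns=["c1", "c2", "c3", "c4"])
E = pd.DataFrame(A @ P.to_numpy(), index=Z.index, columns=P.columns)

print(nca.check_identifiability(Z, 4))
dec = nca.decompose(E, Z, seed=5)
for tf in tfs:
    r = np.corrcoef(dec.P.loc[tf], P.loc[tf])[0, 1]
    print(f"{tf}: |corr(inferred, planted)| = {abs(r):.6f}")

# --- subset consensus over 16 TFs with only 4 conditions --------------------
E2, Z2, design, contrast, changing = consensus_case(seed=42, planted=True)
report = nca.subset_consensus(E2, Z2, design, contrast, seed=42,
                              n_permutations=199)
print(f"\nplanted changing TFs: {sorted(changing)}")
print(f"retained TFs:         {sorted(report.retained)}")
print(report.table[["tf", "mean_contrast", "sign_consistency", "p_perm",
                    "retained"]].head(6).to_string(index=False))

# average each TF's activity over subsets within a biological replicate,
# then summarize across replicates
per_rep = (report.activities
           .groupby(["tf", "condition", "replicate"], as_index=False)["activity"]
           .mean())
ci = nca.activity_ci(per_rep)
print("\nactivity confidence intervals (first rows):")
print(ci.head(4).to_string(index=False))
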