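"""Multiblock sparse PLS-DA across metabolites, taxa and KOs: variable
selection, cross-validated error, AUROC, similarity network and CIM."""

import numpy as np
import pandas as pd

from triomics import chemometrics as chem
from triomics import integration as integ
from triomics import normalize, qa, synth

study = synth.simulate_study(seed=1)
matrix, _ = qa.run_qa(study.matrix, study.meta)
norm, _ = normalize.normalize_pipeline(matrix, study.meta)
roles = study.meta.set_index("sample_id").loc[norm.index, "role"]
sb = normalize.knn_impute(norm.loc[(roles == "study").to_numpy()], k=5)
gens = study.meta.set_index("sample_id").loc[sb.index, "generation"]

blocks = {"metabolites": sb,
          "taxa": np.log1p(study.taxa.loc[sb.index]),
          "kos": np.log1p(study.ko.loc[sb.index])}
model = integ.fit_block_splsda(blocks, gens, ncomp=2, keepX=25)
print("Selected variables per block (component 1):",
      {b: len(model.selected[b][0]) for b in model.block_names})
print("First-component block-score correlations:")
print(model.block_score_correlations(0).round(3))

perf = integ.perf_cv(blocks, gens, ncomp=2, keepX=25, folds=5, repeats=10,
                     seed=0)
print("\n5-fold x 10 classification error:")
print(perf.round(4))
aucs = integ.auroc_table(model)
print("\nOne-vs-all AUROC per block:")
print(aucs.round(4).to_string(index=False))

sim = integ.similarity_matrix(model, blocks, cutoff=0.65)
print(f"\nCross-block similarity edges with |r| > 0.65: {len(sim)}")

sel = []
for b in model.block_names:
    for v in integ.selected_union(model, b):
        sel.append(blocks[b][[v]].rename(columns={v: f"{b}:{v}"}))
cim = integ.cim_cluster(chem.uv_scale(pd.concat(sel, axis=1)))
lab = cim.cut_rows(2)
print("\nCutting the CIM sample dendrogram at 2 clusters:")
print(pd.crosstab(lab, gens))

# The three blocks agree on one dominant infant-vs-adult axis (score
# correlations > 0.9), the Infant one-vs-all AUROC is near 1 in every
# block, and the 2-cluster cut of the clustered image map isolates the
# Infants from both adult generations.
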