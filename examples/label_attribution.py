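"""Separate two ensembles with a self-labelling autoencoder and attribute
the separation to the one distance that actually differs.

Two ensembles share 50 noise distances and differ in a single planted one.
The label model is trained with per-ensemble EM bounds; the learned
per-frame labels are then correlated against every distance.
"""
import numpy as np
from sklearn.metrics import roc_auc_score

from allostate import ensemble, synthdata

Xa, Xb, informative, names = synthdata.generate_attribution_dataset(seed=0)
model = ensemble.train_label_model(Xa, Xb, ensemble.LabelModelConfig(seed=0))

y = np.r_[np.zeros(len(Xa)), np.ones(len(Xb))]
print(f"label AUC between ensembles: {roc_auc_score(y, model.labels):.3f}")

ranking = ensemble.feature_label_correlation(np.vstack([Xa, Xb]), model.labels, names)
print("top 3 distances by |correlation with label|:")
print(ranking.head(3).to_string(index=False))
print(f"planted informative distance: {names[informative]}")
print()
print(
    "An AUC near 1 means the learned activity coordinate separates the\n"
    "ensembles; the planted distance should top the correlation ranking,\n"
    "singling out the structural feature that distinguishes them."
)
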