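"""The four training losses and the evaluation metrics on small tensors.

Focal loss reduces to plain cross-entropy at gamma=0; hard-example mining
keeps only the highest-loss peptides; AUC follows the rank definition with
ties counted half.
"""

import numpy as np

from pephgc import bce_loss, binary_auc, compute_metrics, focal_loss, ohem_loss
from pephgc.losses import inverse_frequency_weights

S = np.array([[0.9, 0.2], [0.6, 0.7], [0.2, 0.4]])
Y = np.array([[1, 0], [1, 1], [0, 0]])

print("cross-entropy:", round(bce_loss(S, Y), 4))
w = inverse_frequency_weights(Y)
print("class weights N/(C*count):", w, "-> weighted CE:", round(bce_loss(S, Y, w), 4))
print("focal gamma=2:", round(focal_loss(S, Y, gamma=2.0), 4),
      " (gamma=0 equals CE:", round(focal_loss(S, Y, gamma=0.0), 4), ")")
print("hard-example mining, keep 2/3:", ohem_loss([3.0, 1.0, 2.0], 2 / 3),
      "= mean of the two largest per-peptide losses")

print("\nAUC of a perfect ranking:", binary_auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]))
print("AUC with one inversion:", binary_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]),
      "(3 of 4 positive-negative pairs concordant)")

rep = compute_metrics(S, Y, threshold=0.5, class_names=["colon", "lung"])
print("\nmacro metrics:", {k: round(getattr(rep, k), 3)
                           for k in ("macro_auc", "acc", "mcc", "prec", "rec", "cell_acc")})
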