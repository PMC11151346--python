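"""Recover a review study's confusion matrix from its printed marginals.

A published evaluation typically prints N, the true-negative count, and
rounded sensitivity/PPV — not the full matrix. ``reconstruct_counts`` runs
an exhaustive integer search for every matrix consistent with those rounded
values; here the solution is unique, and re-deriving the metrics from it
reproduces the printed specificity and F1 as a consistency check.
"""

import plgrouper as pg

rec = pg.reconstruct_counts(n_total=869, tn=37, sensitivity_pct=97.6, ppv_pct=96.8)
c = rec.counts
print(f"unique solution: {rec.unique}")
print(f"tp={c.tp} fp={c.fp} tn={c.tn} fn={c.fn} (total {c.total})")

for name, value in pg.render_metrics(c).items():
    print(f"  {name:<16} {value}")
# sensitivity/PPV reproduce the search constraints by construction;
# specificity, NPV and F1 are independent consequences of the recovered
# integer matrix.
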