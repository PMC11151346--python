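"""Dual-reviewer assessment: categories, adjudication, agreement and κ.

Two raters place each grouped diagnosis into TP/FP/TN/FN; discordant items
get a third-rater tie-break. The script builds a small review set, resolves
it, and prints raw agreement, unweighted Cohen κ, and the confusion-derived
metrics.
"""

import random

import plgrouper as pg
from plgrouper.evaluation import AssessmentCategory as C

rng = random.Random(0)
truth = [C.TP] * 40 + [C.TN] * 5 + [C.FN] * 3 + [C.FP] * 2
# rater A reads truth; rater B misreads a few items
rater_a = list(truth)
rater_b = [c if rng.random() > 0.1 else rng.choice(list(C)) for c in truth]

records = [
    pg.ReviewRecord(f"e{i}", a, b) for i, (a, b) in enumerate(zip(rater_a, rater_b))
]
tiebreaks = {r.entry_id: r.rater_a for r in records if not r.concordant}
resolved = pg.adjudicate(records, tiebreaks)

agree = pg.agreement(rater_a, rater_b)
kappa = pg.cohen_kappa(rater_a, rater_b)
counts = pg.tally(r.final for r in resolved.records)

print(f"n={agree.n_total}, concordant={agree.n_concordant} "
      f"({pg.render_ratio(agree.n_concordant, agree.n_total)}%)")
print(f"adjudicated by third rater: {resolved.n_adjudicated}")
print(f"kappa: po={kappa.po:.3f} pe={kappa.pe:.3f} kappa={kappa.kappa:.3f}")
print(f"final counts: tp={counts.tp} fp={counts.fp} tn={counts.tn} fn={counts.fn}")
print("metrics:", pg.render_metrics(counts))
# κ corrects raw agreement for the agreement expected from the raters'
# marginal category frequencies alone; with one dominant category, κ is
# noticeably lower than the raw proportion.
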