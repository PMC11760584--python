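"""Univariate screening and random-forest feature selection.

Screening reports, per feature, a Kruskal-Wallis p-value (3 classes; a
Mann-Whitney U p-value would be used for 2) and the absolute Spearman
correlation against the class label. Selection keeps the top features of
each family by random-forest impurity importance.
"""

import inkpd
from inkpd.pipeline import extract_table
from inkpd.selection import rf_select, stat_screen

spec = inkpd.CohortSpec(n_per_class=8, duration=4.0, seed=5)
cohort = inkpd.generate_cohort(spec)
table = extract_table(cohort.samples, cohort.labels)

rows = stat_screen(table, table.labels)
print("strongest feature per family (by |rho|):")
seen = set()
for r in sorted(rows, key=lambda r: -r.abs_spearman):
    if r.family in seen:
        continue
    seen.add(r.family)
    print(f"  {r.family:10s} {r.feature:45s} |rho|={r.abs_spearman:.2f} "
          f"p={r.p_value:.2e}")

sel = rf_select(table, table.labels, "kinematic", k=10, seed=0)
print("\ntop-10 kinematic features by forest importance:")
for feat, imp in zip(sel.features, sel.importances):
    print(f"  {feat:45s} {imp:.4f}")
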