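"""Cross-tabulate polygenic versus traditional risk tertiles.

Reproduces the published cross-tabulation arithmetic from the printed
counts of the two population-based studies, then runs the same machinery on
a simulated cohort.
"""

import melanoprs as m

for study in ("australia", "leeds"):
    ct = m.reference_crosstab(study)
    d = m.discordant_cells(ct)
    print(f"{study}: concordance {100 * m.concordance(ct):.0f}% "
          f"(n={ct.n}); low-traditional/high-polygenic "
          f"{100 * d['low_trad_high_prs']:.0f}%, "
          f"high-traditional/low-polygenic {100 * d['high_trad_low_prs']:.0f}%")

manifest = m.default_manifest()
cohort, _ = m.generate_study(
    {"profile": "australia", "effects": "study_like"}, seed=6
)
res = m.crosstab_analysis(cohort, manifest)
print("\nsimulated cohort cross-tabulation (counts):")
print(res["crosstab"].counts)
print(f"concordance {100 * res['concordance']:.0f}%, discordant cells "
      f"{100 * res['discordant']['low_trad_high_prs']:.0f}% / "
      f"{100 * res['discordant']['high_trad_low_prs']:.0f}%")
# Around half of participants get the same low/average/high label from both
# scores; the off-diagonal corners are the people whose genomic and
# phenotypic risk disagree - the motivation for genomic testing.
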