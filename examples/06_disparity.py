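"""The headline worked example: eligibility-incidence (E-I) ratio
disparities recomputed from the packaged published group-counts table
(105 261 ever-smokers, five racial/ethnic groups).

The E-I ratio is screening-eligible participants per incident 6-year lung
cancer case; a lower ratio than the White reference group signals a group
under-served relative to its cancer burden.  Percent differences are taken
on one-decimal-rounded ratios; each group is compared with the reference
by an offset Poisson test at the Bonferroni-adjusted level 0.0125.
"""

from lungscreen import disparity_table, load_packaged_counts
from lungscreen.data_model import RISK_BASED, USPSTF_2021

counts = load_packaged_counts()
results = disparity_table(counts)

for criterion, label in ((USPSTF_2021, "2021 age/smoking rule"),
                         (RISK_BASED, "risk-based (6-year risk >= 1.3%)")):
    print(f"\n{label}")
    print(f"{'group':<20}{'E':>7}{'I':>6}{'E-I':>7}{'% diff':>9}{'p':>11}")
    for r in results:
        if r.criterion != criterion or r.group == "overall":
            continue
        pct = f"{r.percent_difference_vs_reference:+.1f}"
        p = f"{r.p_value:.2e}" if r.p_value > 0 else "<1e-300"
        print(
            f"{r.group:<20}{r.eligible:>7}{r.incident_cases:>6}"
            f"{r.ei_ratio_rounded:>7.1f}{pct:>9}{p:>11}"
        )
print()
print("Under the age/smoking rule the African American E-I ratio (9.5) is 53%")
print("below the White reference (20.3); under risk-based screening the gap")
print("narrows to 15.9 vs 18.4, with minimal differences in the other groups.")
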