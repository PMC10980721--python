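"""Descriptive constituent-ratio summary of a target-drug cohort.

Builds a synthetic corpus, selects the primary-suspect cohort for one
drug, and tabulates gender, age bins, reporter type, country, report
year, serious outcomes and time to onset -- each as a count and a
percentage of the cohort (the constituent ratio).
"""

from pvsignal import CohortSpec, generate_corpus, select_cohort, summarize_cohort
from pvsignal.dedup import dedup_bundle
from pvsignal.synthetic import SimConfig

bundle, _ = generate_corpus(SimConfig(n_reports=4000, n_drugs=20, n_pts=40, seed=11))
bundle, dd = dedup_bundle(bundle)
print(f"after dedup: {len(dd.kept_primaryids)} reports "
      f"({dd.removed_as_duplicate} duplicates, {dd.removed_as_deleted} deleted)")

spec = CohortSpec(drug_keyword="drug005")
cohort = select_cohort(bundle, spec)
summary = summarize_cohort(bundle, cohort, spec)
print(f"cohort: {summary.denominator} reports with DRUG005 as primary suspect\n")

for section, counts in summary.sections():
    print(section)
    for label, count in counts.items():
        print(f"  {label:32s} {count:5d} ({summary.ratio(count):.2f}%)")

print("\nGender, age, reporter, country and year partition the cohort, so")
print("their percentages sum to ~100; outcome rows count reports with")
print("multiplicity and onset rows only reports with complete dates.")
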