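"""Inter-rater reliability of Pfirrmann grading with Cohen's and Fleiss' kappa.

Simulates two ordinal-noisy human raters over a phantom cohort's true
grades and computes the reliability report: per-level Cohen's kappa, their
mean, Fleiss' kappa across three raters (the two humans plus the noiseless
truth standing in for a model), and the agreement-discrepancy histogram.
"""
import pandas as pd

from ivdpipe.phantom import (
    LEVELS, GradeRecord, PhantomSpec, sample_grades, simulate_ratings)
from ivdpipe.raterstats import RatingTable, reliability_report

spec = PhantomSpec(n_patients=120, seed=3)
truth = []
for i in range(spec.n_patients):
    for level, grade in zip(LEVELS, sample_grades(spec, i)):
        truth.append(GradeRecord(f"P{i:04d}", level, int(grade)))

rated = simulate_ratings(truth, ("rater_A", "rater_B"), disagreement_sd=0.45, seed=1)
rows = [{"patient_id": r.patient_id, "level": r.level, "grade": r.grade,
         "rater": r.rater} for r in rated + truth]
table = RatingTable.from_records(pd.DataFrame(rows))

report = reliability_report(table, "rater_A", "rater_B")
print("per-level Cohen's kappa (rater_A vs rater_B):")
for level, kappa in report["per_level_kappa"].items():
    print(f"  {level:>6}: {kappa:.3f}")
print(f"mean over levels: {report['mean_kappa']:.3f}")
print(f"Fleiss' kappa (three raters): {report['fleiss_kappa']:.3f}")

hist = pd.DataFrame(report["histogram"])  # rows: pooled "all" + per level
print("\nagreement histogram (|grade difference| counts):")
print(hist[["exact", "single", "two_plus"]].to_string())
print("\nValues near 0.4-0.6 are the 'moderate agreement' band typical of"
      "\nhuman Pfirrmann grading; exact matches dominate, with single-grade"
      "\ndifferences far more common than larger ones.")
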