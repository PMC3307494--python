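"""Evaluation-metric arithmetic on a curated 216-abstract benchmark.

A curated truth split of 166 A / 50 B with 24 false positives and 4 false
negatives at the 0.5 threshold implies TP=162, TN=26.  This script builds
that confusion matrix through the evaluation module and prints the derived
metrics, including the Matthews correlation coefficient used to summarize
imbalanced two-class results.
"""

from litrank import ConfusionCounts, mcc, precision_recall_fpr
from litrank.evaluation import majority_vote

c = ConfusionCounts(TP=162, FP=24, TN=26, FN=4)
precision, recall, fpr = precision_recall_fpr(c)

print(f"confusion: TP={c.TP} FP={c.FP} TN={c.TN} FN={c.FN}  (n={c.total})")
print(f"correct assignments: {c.TP + c.TN} of {c.total} "
      f"(accuracy {c.accuracy:.1%})")
print(f"precision = {precision:.3f}  recall = {recall:.3f}  fpr = {fpr:.3f}")
print(f"Matthews correlation = {mcc(c):.2f} "
      "(+1 perfect, 0 random, -1 inverted)")

# Majority-vote curation: 122 unanimous-A + 30 unanimous-B + 64 split
# abstracts (44 leaning A, 20 leaning B) give the 166/50 truth split above.
annotations = {}
pmid = 0
for n, labels in ((122, ["A", "A", "A"]), (30, ["B", "B", "B"]),
                  (44, ["A", "A", "B"]), (20, ["B", "B", "A"])):
    for _ in range(n):
        pmid += 1
        annotations[pmid] = labels
voted = majority_vote(annotations)
n_a = sum(lab == "A" for lab, _ in voted.values())
n_ambiguous = sum(amb for _, amb in voted.values())
print(f"majority vote over 3 annotators: {n_a} A / {len(voted) - n_a} B, "
      f"{n_ambiguous} flagged ambiguous")
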