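"""Frozen study reference data shared by the unit and acceptance tests.

The four confusion matrices are the ones implied by the study's printed
correct-classification counts over the balanced 150-image dataset (75/75),
for the 60:40 and 70:30 train/test experiments; the rows are the published
per-class metric tables (percent, 2 decimals, half-even)."""

from mitoboost.metrics import ConfusionSummary

# (confusion, {row: (accuracy_bal, precision, recall, fscore, mcc, gmeasure)})
REFERENCE_TABLES = {
    "train60": (
        ConfusionSummary(tp=39, fn=5, fp=4, tn=42),
        {
            "Mitosis": (88.64, 90.70, 88.64, 89.66, 80.00, 89.66),
            "Nonmitosis": (91.30, 89.36, 91.30, 90.32, 80.00, 90.33),
            "Average": (89.97, 90.03, 89.97, 89.99, 80.00, 89.99),
        },
    ),
    "test40": (
        ConfusionSummary(tp=29, fn=2, fp=0, tn=29),
        {
            "Mitosis": (93.55, 100.00, 93.55, 96.67, 93.55, 96.72),
            "Nonmitosis": (100.00, 93.55, 100.00, 96.67, 93.55, 96.72),
            "Average": (96.77, 96.77, 96.77, 96.67, 93.55, 96.72),
        },
    ),
    "train70": (
        ConfusionSummary(tp=42, fn=8, fp=0, tn=55),
        {
            "Mitosis": (84.00, 100.00, 84.00, 91.30, 85.63, 91.65),
            "Nonmitosis": (100.00, 87.30, 100.00, 93.22, 85.63, 93.44),
            "Average": (92.00, 93.65, 92.00, 92.26, 85.63, 92.54),
        },
    ),
    "test30": (
        ConfusionSummary(tp=22, fn=3, fp=1, tn=19),
        {
            "Mitosis": (88.00, 95.65, 88.00, 91.67, 82.51, 91.75),
            "Nonmitosis": (95.00, 86.36, 95.00, 90.48, 82.51, 90.58),
            "Average": (91.50, 91.01, 91.50, 91.07, 82.51, 91.16),
        },
    ),
}
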