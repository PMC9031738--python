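"""Published per-class metric tables used as worked examples.

Two benchmark tables from the pancreatic-TMA tile-classification study this
package reimplements: per-class precision, recall, F1, Jaccard and support
for the model trained on raw labels (three parenchymal classes) and for the
model trained after communicator clean-up (five classes).  All values are
printed to two decimals, so derived cells must be checked against the
rounding intervals of their inputs, not the point values alone.
"""

# class -> (precision, recall, f1, jaccard, support)
RAW_TABLE = {
    "HLN": (0.89, 0.91, 0.90, 0.82, 874),
    "HP": (0.90, 0.82, 0.86, 0.75, 1690),
    "PDAC": (0.90, 0.94, 0.92, 0.85, 2454),
}
RAW_SUMMARY = {
    "accuracy": 0.90,
    "macro": (0.90, 0.89, 0.89, 0.81),  # precision, recall, f1, jaccard
    "weighted": (0.90, 0.90, 0.90, 0.81),
    "total_support": 5018,
}

CLEANED_TABLE = {
    "ADI": (0.78, 0.55, 0.64, 0.47, 51),
    "BG": (0.95, 0.96, 0.96, 0.92, 908),
    "HLN": (0.92, 0.94, 0.93, 0.87, 758),
    "HP": (0.97, 0.91, 0.94, 0.88, 1277),
    "PDAC": (0.93, 0.96, 0.94, 0.89, 1910),
}
CLEANED_SUMMARY = {
    "accuracy": 0.94,
    "macro": (0.91, 0.86, 0.88, 0.81),
    "weighted": (0.94, 0.94, 0.94, 0.89),
    "total_support": 4904,
}
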