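"""Classify subjects with the published threshold decision rule.

The rule declares a subject low-risk when the HRV triangular index is
preserved (HRVTi > 13.6); with depressed HRVTi, low sample entropy
(< 0.997) or low relative LF power (< 18.1%) flags high risk, and the
residual cases are resolved by absolute LF power and correlation
dimension.
"""

from hrvrisk import RuleTree, rule_tree_classify

subjects = {
    "preserved variability": {
        "HRVTi": 19.2, "SampEn": 2.1, "LF_pct": 40.0, "LF": 0.0012, "CD": 6.0},
    "depressed HRVTi + regular rhythm": {
        "HRVTi": 8.1, "SampEn": 0.71, "LF_pct": 30.0, "LF": 0.0004, "CD": 1.5},
    "depressed HRVTi, low LF share": {
        "HRVTi": 11.0, "SampEn": 1.4, "LF_pct": 9.0, "LF": 0.0003, "CD": 2.2},
    "borderline, saved by high CD": {
        "HRVTi": 12.9, "SampEn": 1.3, "LF_pct": 28.0, "LF": 0.013, "CD": 4.1},
}
tree = RuleTree()  # thresholds 13.6 / 0.997 / 18.1% / 0.011 s^2 / 3.43
for name, feats in subjects.items():
    print(f"{name:38s} -> {rule_tree_classify(feats, tree)}")
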