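"""Orthogonal-assay concordance: 2x2 statistics from per-sample labels.

Recomputes the agreement between sequencing calls and an orthogonal
clinical assay (here: amplification status vs immunohistochemistry, and
a confirmation cohort where every sequencing-positive sample is
re-tested) from per-sample binary labels.
"""

from panelval import concordance

# 15 assay-positive samples, 14 detected by sequencing; 35 negatives agree
ngs = {f"s{i}": i < 14 for i in range(15)} | {f"n{i}": False for i in range(35)}
ihc = {f"s{i}": True for i in range(15)} | {f"n{i}": False for i in range(35)}
res = concordance(ngs, ihc)
print(f"2x2 table: tp={res.tp} fp={res.fp} fn={res.fn} tn={res.tn}")
print(f"sensitivity = {res.fraction('sensitivity')} = {100 * res.sensitivity:.1f}%")
print(f"specificity = {res.fraction('specificity')} = {100 * res.specificity:.1f}%")

# confirmation cohort: every sequencing-positive is re-tested, all confirm
confirm = concordance(
    {f"c{i}": True for i in range(14)},
    {f"c{i}": True for i in range(14)},
    paper_mode=True,
)
print(
    f"confirmation cohort: 'specificity' (PPV over sequencing-positives) = "
    f"{confirm.fraction('specificity')} = {100 * confirm.specificity:.1f}%"
)
# In a cohort restricted to sequencing-positive samples there are no true
# negatives, so assay comparisons quote the positive predictive value
# under the name specificity; paper_mode makes that labeling explicit.
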