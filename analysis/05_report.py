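"""Summary report: estimated constants vs their generative values.

Collects the outputs of stages 01-04 into one human-readable table
(results/report.txt).
"""

import json
from pathlib import Path

from capdep import make_report

OUT = Path(__file__).resolve().parent.parent / "results"

results = {}
lab = OUT / "labeling.json"
if lab.exists():
    d = json.loads(lab.read_text())
    results["photobleach"] = {**d, "f_true": d.get("f_true", 0.779)}
rates = OUT / "rate_constants.json"
if rates.exists():
    d = json.loads(rates.read_text())
    results["traces"] = {
        **d,
        "k_on_true_per_M_per_s": 1.1e7,
        "k_off_true_per_s": 0.45,
    }
mm = OUT / "mm_fit.json"
if mm.exists():
    d = json.loads(mm.read_text())
    results["velocity"] = {
        **d,
        "K_M_true_nM": 50.0,
        "k_cat_true_subunits_per_s": 53.0,
    }
der = OUT / "derived.json"
if der.exists():
    results["derived"] = json.loads(der.read_text())

text = make_report(results)
(OUT / "report.txt").write_text(text)
print(text, end="")
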