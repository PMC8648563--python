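"""Heteromeric receptor complexes and manual curation.

Builds a small WNT/NOTCH-flavoured database, shows the limiting-subunit
(minimum) rule that scores a multimeric receptor by its least-expressed
subunit, and patches the database with a curation table.
"""

import pandas as pd

import nichecomm as nc

db = nc.InteractionDatabase(
    genes=["WNT7A", "FZD5", "LRP6", "JAG1", "NOTCH2"],
    complexes={"WNT_receptor": ["FZD5", "LRP6"]},
    interactions=pd.DataFrame(
        [("I1", "WNT7A", "WNT_receptor", "pathway=WNT"),
         ("I2", "JAG1", "NOTCH2", "pathway=NOTCH")],
        columns=["interaction_id", "partner_a", "partner_b", "annotation"],
    ),
)
print("members of WNT_receptor:", nc.members_of("WNT_receptor", db))

summary = nc.ClusterExpressionSummary(
    mean_expr=pd.DataFrame({"WNT7A": [4.0], "FZD5": [5.0], "LRP6": [1.0],
                            "JAG1": [3.0], "NOTCH2": [2.0]}, index=["epithelium"]),
    frac_expr=pd.DataFrame({"WNT7A": [0.9], "FZD5": [0.5], "LRP6": [0.05],
                            "JAG1": [0.4], "NOTCH2": [0.6]}, index=["epithelium"]),
    n_cells=pd.Series({"epithelium": 100}),
)
mean, frac = nc.partner_summary(summary, "WNT_receptor", "epithelium", db)
print(f"WNT_receptor in epithelium: mean={mean}, frac={frac}")
print("-> limited by LRP6 (frac 0.05 < 0.10): the heteromer does not pass the")
print("   10% expression criterion even though FZD5 alone would.")

patch = pd.DataFrame([{"complex_id": "WNT_receptor", "subunit_1": "FZD5",
                       "subunit_2": "NOTCH2", "action": "replace"}])
patched = nc.apply_curation(db, patch)
print("after curation, members:", nc.members_of("WNT_receptor", patched))
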