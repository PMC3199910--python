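"""Build the ladder of severity from the packaged tables.

For each 5-point CAT score the ladder lists the three unused SGRQ-C items
whose severities sit closest to that score's logit: an ordered sequence of
exemplar health-status effects, from mild (score 5) to very severe (40).
Each item appears at most once, so the steps read as a cumulative ladder.
"""

from catwalk.io import load_table1_conversion, load_table2_items
from catwalk.scenarios import build_ladder

table = load_table1_conversion()
records = load_table2_items()

for step in build_ladder(records, table, step=5, k=3):
    print(f"CAT {step.cat_score:>2} (logit {step.step_logit:+.2f}):")
    for label, logit in step.items:
        print(f"    {label} ({logit:+.2f})")
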