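"""Simulate one isolate's rDNA pileup, call variants, run the filter cascade.

Builds a ~9.1 kb synthetic rDNA unit, spikes three variants at known
intragenomic frequencies (iVFs) into a 3000-fold pileup with 0.1% sequencing
error, then calls and filters. The printed table compares the true spiked
frequencies with the recovered ones; the filter report shows where removed
calls (if any) went.
"""

import pandas as pd

from rdnadiv import (apply_filter_cascade, call_variants, simulate_pileup,
                     synthetic_prototype)
from rdnadiv.simulate import TRUTH_COLUMNS

prototype = synthetic_prototype()

spikes = [(1200, 0.50), (4500, 0.05), (7000, 0.008)]
rows = []
for pos, ivf in spikes:
    ref = prototype.sequence[pos - 1]
    alt = "T" if ref != "T" else "A"
    rows.append(("demo", pos, ref, alt, ivf, prototype.element_of(pos), None, False))
truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)

pileup = simulate_pileup(prototype, truth, coverage=3000, error_rate=0.001, seed=11)
raw = call_variants(pileup, error_rate=0.001, alpha=0.01)
kept, report = apply_filter_cascade(raw, prototype)

print(f"{len(raw)} raw calls, {len(kept)} after the filter cascade")
for rule, n in report.removed.items():
    if n:
        print(f"  removed by {rule}: {n}")
print()
print(f"{'position':>8} {'element':>8} {'true iVF':>9} {'called iVF':>11}")
called = {(c.position, c.alt_seq): c for c in kept}
for row in truth.itertuples(index=False):
    c = called.get((row.position, row.alt))
    got = f"{c.ivf:.4f}" if c else "missed"
    print(f"{row.position:>8} {row.element:>8} {row.true_ivf:>9.4f} {got:>11}")
print()
print("Called iVFs track the spiked frequencies to binomial sampling noise;")
print("a variant on ~1-2 of 200 rDNA copies (iVF 0.008) is still detectable")
print("at this depth.")
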