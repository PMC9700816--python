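"""Structure-stratified selection: iVFP distribution across ribosome shells.

Rebuilds the published worked example from its marginal counts: 875 low-iVF
iVFPs over the large subunit, 7 of them in the innermost shell 1 (82 of 3428
resolved nucleotides). The log10 ratio of observed to expected fractions is
the constrained (<0) vs relaxed (>0) variability metric.
"""

import pandas as pd

from rdnadiv import (shell_skew_test, shell_tally, synthetic_prototype,
                     synthetic_structure_annotation)

prototype = synthetic_prototype()
annotation = synthetic_structure_annotation()

# place 875 low-iVF iVFPs: 7 in shell 1, the rest biased to the outer shells
per_shell = {"1": 7, "2": 50, "3": 100, "4": 150, "5": 200, "6+7": 368}
slots = {}
for (gene, lp), shell in sorted(annotation.shell_of.items()):
    if annotation.subunit_of(gene) == "LSU":
        slots.setdefault(shell, []).append((gene, lp))
rows = []
i = 0
for shell, count in per_shell.items():
    for k in range(count):
        gene, lp = slots[shell][k % len(slots[shell])]
        rows.append({"isolate_id": f"iso{i}", "ref": "A", "alt": "T",
                     "position": prototype.from_gene_coordinate(gene, lp),
                     "ivf": 0.01, "depth": 3000})
        i += 1

tally = shell_tally(pd.DataFrame(rows), annotation, prototype, "LSU", "low")
print(f"{'shell':>6} {'n_i':>6} {'m_i':>5} {'F_i':>7} {'F*_i':>7} {'log10':>7}")
for shell in tally.nucleotides:
    lr = tally.log_ratio(shell)
    print(f"{shell:>6} {tally.nucleotides[shell]:>6} {tally.ivfps[shell]:>5} "
          f"{tally.expected_fraction(shell):>7.4f} "
          f"{tally.observed_fraction(shell):>7.4f} "
          f"{'undef' if lr is None else format(lr, '>7.2f')}")
test = shell_skew_test([tally])
print()
print(f"shell-1 log ratio {tally.log_ratio('1'):.2f} (< 0: constrained; the")
print("innermost shell holds far fewer variants than its nucleotide share")
print(f"predicts). Rank-sum skew test p = {test.loc[0, 'p_adj']:.2e}: the")
print("outward shift of the whole iVFP distribution is significant.")
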