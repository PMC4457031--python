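"""Two-library digital expression analysis with the Poisson exact test.

Simulates gene counts for pooled wild-type and mutant libraries with 100
planted fold changes, calls differentially expressed genes at
FDR <= 0.001 and |log2 ratio| >= 1, merges a second DEG list, and shows
a qPCR-style 2^-ddCt fold change.
"""

import pandas as pd

import recmap
from recmap.expression import call_degs, ddct_fold_change, merge_deg_lists

counts, truth = recmap.simulate_counts(seed=3, n_genes=2000, n_de=100, log2fc=2.0)
print(f"library totals: wild-type {counts.n1:,}, mutant {counts.n2:,}")

deg = call_degs(counts, fdr_max=0.001, min_abs_log2=1.0)
called = deg[deg["call"] != "ns"]
n_up = (called["call"] == "up_in_mutant").sum()
n_down = (called["call"] == "down_in_mutant").sum()
print(f"{len(called)} DEGs called ({n_up} up in mutant, {n_down} down); "
      f"{len(truth.de_log2fc)} were planted")
hits = sum(g in set(called["gene_id"]) for g in truth.de_log2fc)
print(f"sensitivity {hits / len(truth.de_log2fc):.2f}, "
      f"false calls {len(set(called['gene_id']) - set(truth.de_log2fc))}")

# merging a second, partially overlapping DEG list
second_list = list(called["gene_id"].head(20)) + ["novel_1", "novel_2"]
merged = merge_deg_lists(called["gene_id"], second_list)
print(f"merged DEG list: {len(merged)} unique genes "
      f"({(merged['provenance'] == 'both').sum()} shared)")

# qPCR validation arithmetic: ddCt of +1 cycle halves relative expression
qpcr = pd.DataFrame(
    [
        {"gene": "g1", "group": grp, "ct_target": ct, "ct_ref": 15.0}
        for grp, cts in [("wildtype", [20.1, 19.9, 20.0]), ("mutant", [21.0, 21.1, 20.9])]
        for ct in cts
    ]
)
fold = ddct_fold_change(qpcr)
print(f"qPCR 2^-ddCt fold change (mutant vs wild type): {fold['g1']:.2f}")
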