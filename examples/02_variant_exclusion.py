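"""Isolate a causal variant with the recessive exclusion cascade.

Simulates capture-resequencing calls for an affected offspring and its
two carrier parents inside a mapped interval, then applies site QC, the
four-step Mendelian filter, and the non-carrier panel screen.  Finishes
with the downstream molecular checks: an in-silico PCR-RFLP digest and a
premature-stop prediction for a frameshift edit.
"""

import numpy as np

import recmap
from recmap import Interval
from recmap.variant_screen import (
    insilico_rflp,
    mendelian_recessive_filter,
    population_screen,
    predict_truncation,
    variant_site_qc,
)

interval = Interval(chrom="18", start_bp=48_877_373, end_bp=50_901_463)
variants, truth = recmap.simulate_trio_variants(seed=7, interval=interval, n_background=100)
print(f"{len(variants)} called variants in the {interval.length_bp / 1e6:.2f} Mb interval")

after_qc, qc_trace = variant_site_qc(variants)
after_mendel, m_trace = mendelian_recessive_filter(after_qc, "affected", "sire", "dam")
after_panel, p_trace = population_screen(after_mendel, variants.attrs["panel_samples"])

print("\nfilter trace (variants in -> removed):")
for trace in (qc_trace, m_trace, p_trace):
    for step in trace.steps:
        print(f"  {step.name:<26} {step.n_in:>4} -> removed {step.n_removed}")
print(f"\nsurvivor(s): {after_panel['id'].tolist()} "
      f"(planted causal variant: {truth.causal_variant_id})")

# PCR-RFLP genotyping assay: the mutant allele gains a SmaI site
rng = np.random.default_rng(0)
site = "CCCGGG"
backbone = "".join(rng.choice(list("ACGT"), size=891))
while site in backbone:
    backbone = "".join(rng.choice(list("ACGT"), size=891))
mutant = backbone[:435] + site + backbone[441:]
print(f"\nRFLP: wild-type fragments {insilico_rflp(backbone)}, "
      f"mutant fragments {insilico_rflp(mutant)} "
      "(one uncut band vs two cut bands distinguish the alleles)")

# a 1-bp-deletion/2-bp-insertion frameshift truncates the protein
cds = "ATG" + "GCTGAAGGT" * 30 + "TAA"
protein_len, stop_at = predict_truncation(cds, (100, cds[99], "TC"))
print(f"frameshift edit: protein truncated to {protein_len} residues "
      f"(premature stop at residue {stop_at}; full protein is {len(cds) // 3 - 1})")
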