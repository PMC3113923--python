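"""Pairwise differential expression: t-test p-values plus signed fold
changes, combined by the joint rule p < 0.05 AND |FC| > 1.2 (both strict).

Signed fold changes use the negative-reciprocal convention: -2.0 means
halved in the second group, +2.0 doubled, so |FC| >= 1 always.
"""
import metmem as mm

config = mm.SimulationConfig(n_probes=2000, seed=42)
matrix, design, _ = mm.simulate_expression(config)
normalized, _ = mm.normalize(matrix)
filtered, _, _ = mm.detection_filter(normalized, design)

table = mm.run_all_comparisons(filtered, design)
de = mm.de_mask(table)  # ND vs D at p<0.05, |FC|>1.2
print(f"{int(de.sum())} of {len(table.frame)} detected probes are "
      "differentially expressed between non-diabetic and diabetic arms")

probe = table.frame.index[de][0]
stats = table.stats(probe, mm.Group.ND, mm.Group.D)
print(f"\nexample probe {probe}:")
print(f"  p = {stats.p_value:.2e}, signed FC = {stats.signed_fc:+.2f} "
      f"({stats.direction} in diabetic)")
print(f"  group means: ND {stats.mean_a:.1f}, D {stats.mean_b:.1f}")

# The same machinery also evaluates ND-vs-DI and D-vs-DI for every probe;
# those two secondary comparisons drive the insulin-response partition.
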