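"""A small phantom study: vessels per disease regime + group statistics.

Mirrors a multi-venule design: n vessels per group, per-vessel CLN-5
density, ANOVA with Bonferroni-adjusted pairwise comparisons.
"""

import vesselquant as vq

table, stats = vq.run_preset_study(
    ["wt_d16", "astro_ko_d16", "endo_ko_d16"], n_per_group=4, base_seed=0
)

print(table.groupby("group")[["density", "luminal", "perivascular"]].mean().round(2))
print(f"\nANOVA: F = {stats['anova']['F']:.1f}, p = {stats['anova']['p']:.2e}")
for pair, r in stats["pairwise"].items():
    print(f"  {pair}: adjusted p = {r['p_adj']:.2e}")
# expected ranking: astro_ko_d16 > endo_ko_d16 > wt_d16 in density, and
# luminal cells only in the endo_ko group.
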