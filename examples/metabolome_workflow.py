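"""LC-MS metabolite workflow: QC filter, normalization, DEC calling.

Simulates a two-condition intensity table (high vs low glucose, six
replicates each), removes ions with replicate RSD above 30%, equalizes
sample medians, calls differential compounds at fold > 4 / p < 0.01,
and screens a putative identity by 10-ppm mass accuracy.
"""

from glucoshift import (
    AnalysisConfig,
    call_decs,
    normalize_median,
    ppm_match,
    rsd_filter,
    simulate_metabolome,
)

config = AnalysisConfig()
table, truth = simulate_metabolome(n_compounds=409, frac_dec=0.18, rng_seed=7)

filtered, removed = rsd_filter(table, config)
print(f"RSD > {config.rsd_max_percent:.0f}% filter removed {len(removed)} of "
      f"{len(table.compound_ids)} ions")

normalized, factors = normalize_median(filtered)
print(f"median-normalization factors span {factors.min():.3f}-{factors.max():.3f}")

decs = call_decs(normalized, config)
called = [d for d in decs if d.reg_class != "unchanged"]
planted = set(truth.compound_classes.index[truth.compound_classes != "null"])
hits = sum(1 for d in called if d.compound_id in planted)
print(f"DECs called: {len(called)} ({100 * len(called) / len(table.compound_ids):.1f}% "
      f"of the table); {hits} are planted differential compounds")

top = max(called, key=lambda d: abs(d.log2fc))
print(f"strongest DEC: {top.compound_id}, log2FC = {top.log2fc:+.2f}, p = {top.p_value:.1e}")

# identity screening: observed m/z against candidate theoretical masses
candidates = [("riboflavin", 376.1383), ("deoxyguanosine", 267.0968)]
matches = ppm_match(376.1369, candidates, config.ppm_max)
for cid, ppm in matches:
    print(f"m/z 376.1369 matches {cid} at {ppm:.1f} ppm (< {config.ppm_max:.0f} ppm window)")
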