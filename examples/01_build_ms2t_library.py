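"""Build an MS2T feature library from raw aligned feature tables.

A synthetic pair of positive/negative-mode feature tables is generated with
planted QC failures, redundant ion species (isotopes, adducts, dimers,
in-source fragments) and cross-mode twins. The pipeline then:

1. applies the QC filter (reproducibility, sample:blank ratio, RSD, area floor),
2. collapses redundant ion species onto their largest-area parent, and
3. merges the two ionization modes on neutral mass + retention time,

and finally verifies every decision against the generator's ground truth.
"""

from ms2deep import (FixturePlan, MergeParams, merge_modes, qc_filter,
                     remove_redundancy, simulate_feature_table, write_ms2t)

plan = FixturePlan(seed=11, n_features=40)
pos, neg, truth = simulate_feature_table(plan)
print(f"simulated {len(pos)} positive and {len(neg)} negative features")
print(f"planted: {len(truth['qc_fail'])} QC failures, "
      f"{len(truth['redundant'])} redundant ions, "
      f"{len(truth['merge_pairs'])} cross-mode twins")

# 1. quality control
kept_pos, report = qc_filter(pos)
kept_neg, _ = qc_filter(neg)
failed = {fid: reasons for fid, reasons in report.items() if reasons}
print(f"\nQC removed {len(failed)} features:")
for fid, reasons in sorted(failed.items())[:4]:
    print(f"  {fid}: {', '.join(reasons)}")
print(f"  ... ({len(failed) - 4} more)")
assert set(failed) == set(truth["qc_fail"])

# 2. redundancy removal (isotopes, adducts, dimers, in-source fragments)
survivors, removed = remove_redundancy(kept_pos)
print(f"\nredundancy removal dropped {len(removed)} ion species:")
for r in removed:
    print(f"  {r.feature.id}: {r.kind} of {r.parent_id} "
          f"({r.ppm_error:.2f} ppm)")
assert {r.feature.id: (r.kind, r.parent_id) for r in removed} == truth["redundant"]

# 3. cross-mode merging into MS2T entries
entries = merge_modes(survivors, kept_neg, MergeParams())
merged = [(e.feature.id, e.partner_id) for e in entries if e.partner_id]
print(f"\n{len(entries)} MS2T entries; merged cross-mode pairs:")
for a, b in merged:
    print(f"  {a} <-> {b}")
assert set(merged) == set(truth["merge_pairs"])

write_ms2t(entries, "scratch_ms2t.tsv")
print("\nwrote scratch_ms2t.tsv (+ companion .msp with MS2 spectra)")
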