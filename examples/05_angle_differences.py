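"""Per-residue circular angle differences between resistant and sensitive
ensembles, with the wild-type-derived 15-degree magnitude gate.

For every backbone dihedral the circular means of the two classes are
differenced (respecting wraparound) and Welch-tested; an angle is
flagged when the difference exceeds the threshold AND is significant.
"""

import angleforest as af

spec = af.make_planted_study(
    "dabrafenib", planted=["phi455", "psi460"], offset=60.0, seed=0,
    n_residues=60, residue_offset=448,
    frames_per_trajectory=300, retain_last=100)
known, _ = af.build_data_matrix(
    af.generate_study(spec), spec.label_table("dabrafenib"), "dabrafenib")

# data-driven threshold from the wild-type reference ensemble
wt = known.select_variants(["WT"])
print(f"wild-type dispersion scale: {af.wt_threshold(wt):.1f} degrees "
      f"(the published analysis used 15)")

table = af.group_angle_analysis(known, threshold=15.0, alpha=0.05)
flagged = table[table["flag"]]
print(f"\nangles flagged (|diff| > 15 deg AND p < 0.05): "
      f"{flagged['feature'].tolist()}")
print(flagged[["feature", "mean_S", "mean_R", "diff", "p"]]
      .round(3).to_string(index=False))
# Only the planted angles should survive the magnitude gate; the t-test
# alone would flag ~5% of null angles by chance.
sig_only = table["significant"].sum()
print(f"\nsignificant before the magnitude gate: {sig_only} angles; "
      f"after: {len(flagged)}")
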