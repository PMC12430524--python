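"""Generate a small synthetic BRAF variant study and build the data matrix.

The generator mirrors the real study design — the 16-variant clinical
roster, three trajectories per variant with only the final frames
retained, von Mises per-angle fluctuations, and a handful of planted
angles whose circular means differ by 60 degrees between the resistant
and sensitive classes — at a reduced frame count so it runs in seconds.
"""

import angleforest as af

spec = af.make_planted_study(
    "dabrafenib",
    planted=["phi455", "psi460"],   # class-discriminative angles
    offset=60.0,                    # degrees between class means
    seed=0,
    n_residues=60, residue_offset=448,
    frames_per_trajectory=300, retain_last=100)

ensembles = af.generate_study(spec)
labels = spec.label_table("dabrafenib")
known, unknown = af.build_data_matrix(ensembles, labels, "dabrafenib")

print(f"variants simulated : {len(ensembles)}")
print(f"frames per variant : {ensembles[0].n_frames} "
      f"(3 trajectories x last {spec.retain_last} of "
      f"{spec.frames_per_trajectory} frames)")
print(f"training matrix    : {known.n_rows} rows x "
      f"{len(known.feature_names)} angle columns "
      f"(12 variants with a known label)")
print(f"prediction matrix  : {unknown.n_rows} rows "
      f"(4 variants of uncertain significance)")
# The training matrix rows are individual conformations; the columns are
# backbone phi/psi angles in degrees named by kinase residue number.
print("first angle columns:", known.feature_names[:4], "...")
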