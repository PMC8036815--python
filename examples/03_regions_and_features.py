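"""Partition a slide into core / invasive front and assemble features.

The invasive front is the ±500 μm band around the tumour border; the 201
features are 126 image (counts and densities of 21 populations × 3
regions), 60 spatial (10 L-curves × 6 radii) and 15 clinical values.
"""

import immunocontext as ic
from immunocontext.regions import assign_regions

config = ic.CohortConfig(n_patients=3, seed=2)
cohort = ic.generate_cohort(config)
patient = cohort[0]

part = patient.partition
print("region areas (mm²):", {k: round(v, 2) for k, v in part.areas.items()})

cells = patient.cells.copy()
cells["region"] = assign_regions(cells["x_um"], cells["y_um"], part)
print("cells per region:\n", cells["region"].value_counts().to_string())

features = ic.assemble_features(cohort)
print("\nfeature matrix:", features.shape)  # (3 patients, 201 features)
row = features.iloc[0]
print("TB density in core (per mm²):", round(row["TB_any_core_density"], 2))
print("CD8 L(50) around TBs (μm):", round(row["L_TB_CD8_r50"], 1))
# L(50) ≈ 50 means CD8 cells are randomly placed around buds at that
# scale; larger values indicate clustering, smaller ones avoidance.
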