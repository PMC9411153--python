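"""From patches to per-patient MIL bags.

Encodes each retained 256-px patch with the deterministic synthetic encoder
(256 px @0.25 µm -> downsample -> 128 px @0.5 µm -> 128-dim vector), groups
adjacent vectors into 2x2x128 super-patches representing 512-px areas, and
pools instances across a patient's cores into one labelled bag.
"""

from milsurv import (
    SyntheticEncoder,
    assemble_superpatches,
    build_bags,
    compute_tissue_mask,
    encode_patch,
    extract_patch_grid,
    simulate_core_image,
)
from milsurv.cohort import PatientRecord, SurvivalLabel

encoder = SyntheticEncoder(d=128, seed=0)
cohort, store = [], {}
for i in range(2):  # two patients, two cores each
    cores = []
    for j in range(2):
        core_id = f"P{i}_core{j}"
        core, _ = simulate_core_image(1536, 1536, seed=10 * i + j, core_id=core_id)
        grid = extract_patch_grid(compute_tissue_mask(core), 256, 0.5)
        feats = {
            (r, c): encode_patch(core.pixels[r : r + 256, c : c + 256], encoder)
            for (r, c) in grid.origins
        }
        store[core_id] = assemble_superpatches(grid, feats, core_id=core_id)
        cores.append(core_id)
        print(f"{core_id}: {len(grid)} patches -> {len(store[core_id])} super-patches")
    cohort.append(PatientRecord(f"P{i}", tuple(cores), SurvivalLabel(4.3, i % 2)))

bags = build_bags(cohort, store)
for bag in bags:
    print(
        f"{bag.patient_id}: bag of {len(bag)} instances of dim "
        f"{bag.instances[0].vector.size} (grid {bag.instances[0].grid_shape}), "
        f"label (t={bag.label.time}, delta={bag.label.event})"
    )
# Each bag is one training example: hundreds of patch embeddings sharing a
# single survival label — the core premise of the MIL formulation.
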