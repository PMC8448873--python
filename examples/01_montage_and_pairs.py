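"""Electrode geometry: build the spherical 10-10 montage and select pairs.

Builds the default montage, measures a few inter-electrode chord distances,
and applies the analysis pair-selection rules (frontal/temporal/parietal
region of interest, peripheral exclusion, 6 cm minimum separation).
"""

from thetasync.montage import candidate_pairs, load_standard_montage, pair_distance

montage = load_standard_montage()
print(f"montage: {len(montage.labels)} channels on a "
      f"{montage.head_radius_cm} cm sphere; Cz at {montage.position('Cz')}")

for a, b in [("Fz", "Pz"), ("AF4", "FT8"), ("T8", "CP5"), ("C3", "C1")]:
    print(f"chord {a}-{b}: {pair_distance(montage, a, b):5.2f} cm")

pairs = candidate_pairs(montage)
print(f"\nanalysis set: {len(pairs)} pairs from {len(pairs.roi_labels)} ROI "
      f"electrodes (min separation {pairs.min_distance_cm} cm,")
print(f"excluded: {', '.join(pairs.excluded_labels)})")
print("C3-C1 kept?", ("C3", "C1") in pairs, "- short links reflect volume "
      "conduction and are dropped")
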