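"""Compare ITS heterogeneity profiles across sponge specimens.

Uses the published measurement tables bundled with the package: replicate
statistics for one specimen under varying PCR conditions, and the profile
comparison between a same-strain pair (Pe1/Pe2) and a different-strain pair
(V1/V2).
"""

from tracemix import datasets
from tracemix.profiling import (
    count_distinguishing_features,
    distinguishing_features,
    replicate_stats,
)

# repeatability: the 253-nt variant over seven PCR conditions
stats = replicate_stats(datasets.V2_REPLICATES["len253"], datasets.V2_REFERENCE_SUBSET)
print(f"253-nt percentage, mean of the three 100 ng replicates: {stats.reference_mean:.2f}")
print(f"three-replicate range: {stats.range_over([0, 1, 2]):.2f} points (permitted error: 5)")
for i, cond in enumerate(datasets.V2_PCR_CONDITIONS):
    print(f"  {cond:>13}: {stats.values[i]:6.2f}  (deviation {stats.deviations[i]:.2f})")

# strain discrimination
v1, v2 = datasets.strain_profile("V1"), datasets.strain_profile("V2")
pe1, pe2 = datasets.strain_profile("Pe1"), datasets.strain_profile("Pe2")
print(f"\nV1 vs V2 (different strains): "
      f"{count_distinguishing_features(v1, v2)} distinguishing features")
feats = distinguishing_features(pe1, pe2, criterion="margin")
print(f"Pe1 vs Pe2 (same strain), differences beyond permitted error: {len(feats)}")
for region, kind, key in feats:
    print(f"  {region} {kind} {key}")
print("same-strain differences are confined to ITS2 length proportions.")
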