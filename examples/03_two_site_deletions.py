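"""Resolve per-site deletion fractions for a region with two indel sites.

ITS2 carries two T-track deletion sites (around positions 13 and 246-247).
A reverse-primer read fits the near site directly over the window between
the sites, fits the total-length distribution downstream of the far site,
and infers the far site's deletion percentage from the conservation
identity d_near + d_far = 2 P(L-2) + P(L-1).
"""

import numpy as np

from tracemix import pipeline
from tracemix.signal_prep import normalize_direct_read
from tracemix.synthetic import (
    GeneratorConfig,
    clone_set,
    make_reference,
    reference_in_read_frame,
    simulate_direct_read,
    site_in_read_frame,
)

cfg = GeneratorConfig(seed=3)
rng = np.random.default_rng(cfg.seed)
reference = make_reference(cfg)

# reverse-primer calibration: clones read 3'->5', so the profile lives in
# the reverse read frame
clones = clone_set(reference, cfg, rng, direction="reverse")
ref_rev = reference_in_read_frame(reference, "reverse")
sites_rev = sorted(
    (site_in_read_frame(s, "reverse", reference.length) for s in reference.sites),
    key=lambda s: s.start,
)
profile = pipeline.intrinsic_from_clones(clones, ref_rev, sites_rev)

# ground truth: per-molecule deletion states (site-13 shift, site-247 shift)
states = {(-1, -1): 0.20, (-1, 0): 0.12, (0, -1): 0.13, (0, 0): 0.55}
truth_d13 = 100 * sum(p for (a, _), p in states.items() if a < 0)
truth_d247 = 100 * sum(p for (_, b), p in states.items() if b < 0)

far, near = reference.sites_in_region("ITS2")
idx = {s.start: i for i, s in enumerate(reference.sites)}
table = simulate_direct_read(
    reference,
    [({idx[far.start]: a, idx[near.start]: b}, p) for (a, b), p in states.items()],
    cfg,
    rng,
    direction="reverse",
)
observed = normalize_direct_read(table, (0, len(table)))

near_r = site_in_read_frame(near, "reverse", reference.length)
far_r = site_in_read_frame(far, "reverse", reference.length)
near_est, total_est, d_near, d_far, length_pct, _ = pipeline.analyze_two_site_region(
    observed, profile, near_r, far_r, reference.annotation.its2_length,
    near_shifts=[-1, 0], total_shifts=[-2, -1, 0],
)

print("ITS2 total length distribution (fit downstream of both sites):")
for length, pct in sorted(length_pct.items()):
    print(f"  {length} nt: {pct:.1f}%")
print(f"site 247 deletion (measured):  {d_near:.0f}%  (truth {truth_d247:.0f}%)")
print(f"site 13 deletion  (inferred):  {d_far:.0f}%  (truth {truth_d13:.0f}%)")
print("the inferred value uses only the length distribution and the measured site.")
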