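"""End-to-end wiring: clone calibration, per-sample analysis, profile assembly.

These functions connect the pieces in the order a sequencing analyst would:
normalize clone reads and build per-direction intrinsic profiles; gate each
direct read on noise; fit length-variant proportions per indel site;
quantify substitutions (clean or mixed-region); infer joint per-site
deletion fractions for two-site regions; and assemble thresholded ITS
profiles.  The command-line interface and the example scripts are thin
shells over this module.
"""

from __future__ import annotations

from .intrinsic import (
    CloneAlignment,
    IndelSite,
    IntrinsicProfile,
    align_clones,
    build_intrinsic_profile,
)
from .mixture import (
    LengthVariant,
    LengthVariantSet,
    MixtureEstimate,
    enumerate_variants,
    fit_proportions,
    infer_joint_site_proportions,
)
from .profiling import ITSProfile, apply_thresholds
from .signal_prep import (
    NoiseReport,
    NormalizedSignals,
    assess_noise,
    normalize_clone_read,
)
from .substitutions import (
    NoCallError,
    SubstitutionCall,
    quantify_substitution,
    quantify_substitution_mixed,
)
from .trace_io import CallPointTable


def intrinsic_from_clones(
    clone_tables: dict[str, CallPointTable],
    reference_seq: str,
    sites: list[IndelSite],
    region: tuple[int, int] | None = None,
) -> IntrinsicProfile:
    """Normalize clone reads and average them into an intrinsic profile.

    `reference_seq` and `sites` must be in the clones' read frame (i.e. the
    reverse complement for reverse-primer clones); the resulting profile is
    then directly comparable to direct reads taken with the same primer.
    """
    normalized: dict[str, NormalizedSignals] = {}
    seqs: dict[str, str] = {}
    for cid, table in clone_tables.items():
        reg = region or (0, len(table))
        normalized[cid] = normalize_clone_read(table, reg)
        seqs[cid] = table.sequence
    alignment: CloneAlignment = align_clones(seqs, reference_seq, sites)
    return build_intrinsic_profile(normalized, alignment)


def fit_site_lengths(
    direct: NormalizedSignals,
    profile: IntrinsicProfile,
    site: IndelSite,
    region_length: int,
    max_indel: int = 2,
    shifts: list[int] | None = None,
    window: tuple[int, int] | None = None,
    grid_step: float = 0.01,
) -> MixtureEstimate:
    """Fit length-variant proportions at one homopolymer site.

    Variants default to every shift in [-max_indel, +max_indel] that the
    track allows, labelled by resulting region length.
    """
    if shifts is None:
        variants = enumerate_variants(profile.reference, site, max_indel, region_length=region_length)
    else:
        variants = LengthVariantSet(
            site=site,
            variants=sorted(
                (LengthVariant(label=str(region_length + s), shift=s) for s in shifts),
                key=lambda v: v.shift,
            ),
        )
    return fit_proportions(direct, profile, variants, window=window, grid_step=grid_step)


def lengths_to_percentages(estimate: MixtureEstimate, decimals: int | None = 2) -> dict[int, float]:
    """Region-length percentages from a fit, keyed by length in nt."""
    out = {}
    for lab, frac in estimate.proportions.items():
        pct = 100.0 * frac
        out[int(lab)] = round(pct, decimals) if decimals is not None else pct
    return out


def two_site_deletions(
    measured_site_estimate: MixtureEstimate,
    total_length_estimate: MixtureEstimate,
    region_length: int,
) -> tuple[float, float, dict[int, float]]:
    """Per-site deletion percentages for a region with two 1-nt deletion sites.

    The site nearest the primer is measured directly (its fit gives the
    fraction of molecules deleted there); the far site follows from the
    total-length distribution by the conservation identity
    d_near + d_far = 2 P(L-2) + P(L-1).
    Returns (near_site_pct, far_site_pct, length_pct).
    """
    d_near = 100.0 * sum(
        frac
        for lab, frac in measured_site_estimate.proportions.items()
        if int(lab) < region_length
    )
    length_pct = lengths_to_percentages(total_length_estimate)
    d_far = infer_joint_site_proportions(length_pct, d_near)
    return d_near, d_far, length_pct


def call_substitution_clean(
    direct: NormalizedSignals,
    profile: IntrinsicProfile,
    position: int,
    base_x: str,
    base_y: str,
    region_label: str = "",
    report_position: int | None = None,
) -> SubstitutionCall:
    """Clean-position substitution quantification with intrinsic correction.

    Expected intensities come from clones carrying each base when available,
    else from the consensus value at the position.
    """
    return quantify_substitution(
        direct,
        position,
        base_x,
        base_y,
        expected_x=profile.expected_for(position, base_x),
        expected_y=profile.expected_for(position, base_y),
        region_label=region_label,
        report_position=report_position,
    )


def analyze_two_site_region(
    direct: NormalizedSignals,
    profile: IntrinsicProfile,
    near_site: IndelSite,
    far_site: IndelSite,
    region_length: int,
    near_shifts: list[int],
    total_shifts: list[int],
    mixed_substitutions: list[tuple[int, str]] = (),
) -> tuple[MixtureEstimate, MixtureEstimate, float, float, dict[int, float], list[SubstitutionCall]]:
    """Full two-deletion-site analysis of one read direction.

    Fits the near site over the window between the two sites, then the total
    length downstream of the far site, infers the far site's deletion
    percentage, and finally quantifies any substitutions lying in the mixed
    region between the sites against the fitted near-site mixture.
    """
    near_est = fit_site_lengths(
        direct,
        profile,
        near_site,
        region_length,
        shifts=near_shifts,
        window=(near_site.start, min(far_site.start, near_site.end + 250)),
    )
    total_variants = LengthVariantSet(
        site=far_site,
        variants=sorted(
            (LengthVariant(label=str(region_length + s), shift=s) for s in total_shifts),
            key=lambda v: v.shift,
        ),
    )
    total_est = fit_proportions(direct, profile, total_variants)
    d_near, d_far, length_pct = two_site_deletions(near_est, total_est, region_length)
    calls: list[SubstitutionCall] = []
    # probe each substitution at the dominant frame's read coordinate
    s_dom = max(near_est.variants.variants, key=lambda v: near_est.proportions[v.label]).shift
    for ref_pos, label in mixed_substitutions:
        read_pos = ref_pos + s_dom if ref_pos > near_site.end else ref_pos
        try:
            calls.append(
                quantify_substitution_mixed(
                    direct, near_est, profile, read_pos, region_label=label
                )
            )
        except NoCallError:
            pass
    return near_est, total_est, d_near, d_far, length_pct, calls


def assemble_profile(
    sample_id: str,
    its1_lengths: dict[int, float] | None = None,
    its2_lengths: dict[int, float] | None = None,
    substitutions: list[tuple[str, int, str, float]] = (),
    deletions: dict[str, dict[int, float]] | None = None,
    qc: dict | None = None,
    length_threshold: float = 5.0,
    substitution_threshold: float = 10.0,
) -> ITSProfile:
    """Assemble raw percentages into a thresholded ITSProfile.

    substitutions are (region, 1-based position, base, percent) tuples.
    """
    raw = ITSProfile(sample_id=sample_id, qc=qc or {})
    if its1_lengths:
        raw.length_pct["ITS1"] = dict(its1_lengths)
    if its2_lengths:
        raw.length_pct["ITS2"] = dict(its2_lengths)
    for region, pos, base, pct in substitutions:
        raw.substitution_pct.setdefault(region, {})[(pos, base)] = pct
    for region, d in (deletions or {}).items():
        raw.deletion_pct[region] = dict(d)
    return apply_thresholds(raw, length_threshold, substitution_threshold)


def gate_read(
    table: CallPointTable,
    clean_region: tuple[int, int],
    threshold: float = 0.10,
) -> NoiseReport:
    """Noise QC for one direct read over a caller-designated clean region."""
    return assess_noise(table, clean_region, threshold)
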