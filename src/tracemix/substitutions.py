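"""Quantify two-base substitution mixtures from direct-read peak heights.

At a clean position, the fraction carrying base X is the observed X-channel
intensity divided by its intrinsic expectation, normalized against the same
ratio for the other base; this corrects for the strong context dependence of
peak heights.  Inside a frame-shifted mixed region the expected background
of every channel is first simulated from the fitted length-variant mixture,
and the substitution is read off the residual excess.  Substitution results
rest on a single position, so they are always rounded to integer percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .intrinsic import IntrinsicProfile
from .mixture import MixtureEstimate, simulate_mixture
from .signal_prep import NormalizedSignals
from .trace_io import BASES

SUBSTITUTION_THRESHOLD = 10.0  # percent


class NoCallError(ValueError):
    """Raised when the observed signal is too weak or shows no excess to call."""


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class SubstitutionCall:
    region_label: str
    position: int  # 1-based within the region (or read, caller's frame)
    base_major: str
    base_minor: str
    percent_major: int
    percent_minor: int
    method: str  # "clean" | "mixed_region"
    passed_threshold: bool

    def percent(self, base: str) -> int:
        if base == self.base_major:
            return self.percent_major
        if base == self.base_minor:
            return self.percent_minor
        raise KeyError(base)


def quantify_substitution(
    observed: NormalizedSignals,
    position: int,
    base_x: str,
    base_y: str,
    expected_x: float,
    expected_y: float,
    region_label: str = "",
    report_position: int | None = None,
    noise_floor: float = 0.0,
    threshold: float = SUBSTITUTION_THRESHOLD,
) -> SubstitutionCall:
    """Peak-height quantification at a clean (unshifted) position.

    fraction(X) = (I_X / E_X) / (I_X / E_X + I_Y / E_Y) with I the observed
    window intensities and E the intrinsic expectations; when E_X = E_Y this
    reduces to the raw peak-height ratio.
    """
    if expected_x <= 0 or expected_y <= 0:
        raise ValueError("expected intensities must be positive")
    i_x = float(observed.values[position, BASES.index(base_x)])
    i_y = float(observed.values[position, BASES.index(base_y)])
    if i_x <= noise_floor and i_y <= noise_floor:
        raise NoCallError(f"both channels at position {position} below the noise floor")
    rx = i_x / expected_x
    ry = i_y / expected_y
    pct_x = _round_half_away(100.0 * rx / (rx + ry))
    pct_y = 100 - pct_x
    if pct_x >= pct_y:
        major, minor, pm, pn = base_x, base_y, pct_x, pct_y
    else:
        major, minor, pm, pn = base_y, base_x, pct_y, pct_x
    return SubstitutionCall(
        region_label=region_label,
        position=report_position if report_position is not None else position + 1,
        base_major=major,
        base_minor=minor,
        percent_major=pm,
        percent_minor=pn,
        method="clean",
        passed_threshold=pn >= threshold,
    )


def quantify_substitution_mixed(
    observed: NormalizedSignals,
    mixture: MixtureEstimate,
    profile: IntrinsicProfile,
    position: int,
    region_label: str = "",
    report_position: int | None = None,
    noise_floor: float = 50.0,
    threshold: float = SUBSTITUTION_THRESHOLD,
) -> SubstitutionCall:
    """Quantify a substitution inside a frame-shifted mixed region.

    The fitted mixture predicts a background intensity for every channel at
    the position; the substitution candidate is the base with the largest
    positive observed excess over that background.  The excess is converted
    to a molecule fraction against the expected intensity of that base at
    the substituted reference coordinate (the dominant frame's coordinate),
    using the allele-specific intrinsic value when clones carrying the base
    were sequenced and the consensus value otherwise.
    """
    from .mixture import _variant_ref_position

    p = np.array([mixture.proportions[lab] for lab in mixture.variants.labels])
    sim = simulate_mixture(profile, mixture.variants, p, positions=np.array([position]))
    background = sim.values[0]
    if not sim.valid[0]:
        raise ValueError(f"position {position} is outside the calibrated mixture window")
    excess = observed.values[position] - background
    cand = int(np.argmax(excess))
    if excess[cand] <= noise_floor:
        raise NoCallError(f"no channel exceeds the mixture background at position {position}")
    dominant = max(mixture.variants.variants, key=lambda v: mixture.proportions[v.label])
    ref_coord = _variant_ref_position(position, dominant.shift, mixture.variants.site)
    expected_alt = profile.expected_for(ref_coord, BASES[cand])
    pct_minor = _round_half_away(100.0 * float(excess[cand]) / expected_alt)
    pct_minor = max(0, min(100, pct_minor))
    # the displaced (background-dominant) base is reported as the partner
    partner = int(np.argmax(background))
    return SubstitutionCall(
        region_label=region_label,
        position=report_position if report_position is not None else position + 1,
        base_major=BASES[cand] if pct_minor > 50 else BASES[partner],
        base_minor=BASES[partner] if pct_minor > 50 else BASES[cand],
        percent_major=max(pct_minor, 100 - pct_minor),
        percent_minor=min(pct_minor, 100 - pct_minor),
        method="mixed_region",
        passed_threshold=pct_minor >= threshold,
    )
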