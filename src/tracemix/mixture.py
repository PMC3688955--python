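"""The proportion model: fit relative abundances of length variants.

A direct Sanger read of a mixed amplicon superposes every template variant.
Variants that differ by an indel in a homopolymer track read identically up
to the track and then diverge into shifted frames: a variant with signed
length shift s shows, at read position u downstream of the track, the base
the reference carries at position u - s.  Given an intrinsic profile of
expected per-position intensities, the expected signal of any hypothesized
mixture is the proportion-weighted superposition of the shifted profiles.
Fitting compares these simulations against the observed direct read over a
window of at least 200 positions after the indel and keeps the best one.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .intrinsic import IndelSite, IntrinsicProfile
from .signal_prep import NormalizedSignals
from .trace_io import BASES

DEFAULT_MIN_WINDOW = 200
HARD_MIN_WINDOW = 50


@dataclass(frozen=True)
class LengthVariant:
    label: str
    shift: int  # signed nt difference vs the reference (deletion < 0)


@dataclass
class LengthVariantSet:
    """Candidate length variants at one homopolymer indel site."""

    site: IndelSite
    variants: list[LengthVariant]
    region_label: str = ""

    def __post_init__(self) -> None:
        shifts = [v.shift for v in self.variants]
        if len(set(shifts)) != len(shifts):
            raise ValueError("variant shifts must be distinct")
        if 0 not in shifts:
            raise ValueError("the reference variant (shift 0) must be present")
        for s in shifts:
            if s < -self.site.length:
                raise ValueError(f"shift {s} would delete more than the {self.site.length}-nt track")

    @property
    def labels(self) -> list[str]:
        return [v.label for v in self.variants]

    @property
    def shifts(self) -> list[int]:
        return [v.shift for v in self.variants]


@dataclass
class ShiftStateSpace:
    """Compound frames over several indel sites ordered along the read.

    Each state is a tuple of per-site shifts; the frame offset downstream of
    site k is the cumulative sum of the first k shifts.
    """

    sites: list[IndelSite]
    states: list[tuple[int, ...]]

    def __post_init__(self) -> None:
        starts = [s.start for s in self.sites]
        if starts != sorted(starts):
            raise ValueError("sites must be ordered along the read")
        for st in self.states:
            if len(st) != len(self.sites):
                raise ValueError("state arity must match the number of sites")

    @classmethod
    def from_site_shifts(cls, sites: list[IndelSite], per_site_shifts: list[list[int]]) -> "ShiftStateSpace":
        return cls(sites=sites, states=[tuple(t) for t in itertools.product(*per_site_shifts)])

    def cumulative_shift(self, state: tuple[int, ...], after_site: int) -> int:
        return int(sum(state[: after_site + 1]))

    def total_shift(self, state: tuple[int, ...]) -> int:
        return int(sum(state))


def enumerate_variants(
    reference: str,
    site: IndelSite,
    max_indel: int,
    region_length: int | None = None,
    region_label: str = "",
) -> LengthVariantSet:
    """Enumerate length variants with shifts in [-max_indel, +max_indel].

    Labels are the resulting region length when `region_length` is given
    (the field convention, e.g. '253' for a 1-nt deletion in a 254-nt ITS1),
    else the signed shift.
    """
    track = reference[site.start : site.end]
    if track != site.base * site.length:
        warnings.warn(
            f"declared site {site.start + 1}-{site.end} is not a pure {site.base}-track",
            stacklevel=2,
        )
    is_maximal = (site.start == 0 or reference[site.start - 1] != site.base) and (
        site.end >= len(reference) or reference[site.end] != site.base
    )
    if not is_maximal:
        warnings.warn("indel site is not a maximal homopolymer run", stacklevel=2)
    variants = []
    for shift in range(-max_indel, max_indel + 1):
        if site.length + shift < 0:
            continue
        if region_length is not None:
            label = str(region_length + shift)
        else:
            label = f"{shift:+d}" if shift else "0"
        variants.append(LengthVariant(label=label, shift=shift))
    return LengthVariantSet(site=site, variants=variants, region_label=region_label)


@dataclass
class ExpectedSignal:
    """Simulated per-position per-base expected intensities for a mixture."""

    values: np.ndarray  # (n_positions, 4), base order A,C,G,T
    valid: np.ndarray  # (n_positions,) bool: all variants calibrated here
    start: int = 0

    @property
    def position_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)


def _variant_ref_position(u: int, shift: int, site: IndelSite) -> int:
    """Reference position whose intrinsic value a shift-s variant shows at read
    position u.  Within the shortened/lengthened track the context is the track
    itself; downstream the frame is offset by -shift."""
    if u < site.start:
        return u
    var_track_end = site.start + site.length + shift
    if u < var_track_end:
        return min(u, site.end - 1)
    return u - shift


def _contribution_matrices(
    profile: IntrinsicProfile,
    variants: LengthVariantSet,
    positions: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant expected-signal matrices over `positions`.

    Returns (M, valid): M[v, i, c] is variant v's intrinsic intensity routed
    to channel c at read position positions[i]; valid[i] is False where any
    variant maps outside the calibrated profile.
    """
    k = len(variants.variants)
    n = len(positions)
    M = np.zeros((k, n, 4))
    valid = np.ones(n, dtype=bool)
    calibrated = profile.calibrated & np.isfinite(profile.expected)
    for vi, var in enumerate(variants.variants):
        for i, u in enumerate(positions):
            rp = _variant_ref_position(int(u), var.shift, variants.site)
            if rp < 0 or rp >= len(profile) or not calibrated[rp]:
                valid[i] = False
                continue
            base = profile.consensus[rp]
            if base not in "ACGT":
                valid[i] = False
                continue
            M[vi, i, BASES.index(base)] = profile.expected[rp]
    return M, valid


def simulate_mixture(
    profile: IntrinsicProfile,
    variants: LengthVariantSet,
    proportions: np.ndarray | list[float],
    positions: np.ndarray | None = None,
) -> ExpectedSignal:
    """Superpose shifted intrinsic profiles according to mixture proportions.

    Upstream of the indel site every variant contributes identically; from
    the site on, each variant with shift s routes the intrinsic value of
    reference position u - s to the base found there.  The result is linear
    in the proportions.
    """
    p = np.asarray(proportions, dtype=float)
    if p.shape != (len(variants.variants),):
        raise ValueError("one proportion per variant required")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"proportions must sum to 1, got {p.sum():.8f}")
    if np.any(p < -1e-12):
        raise ValueError("proportions must be non-negative")
    if positions is None:
        positions = np.arange(len(profile))
    positions = np.asarray(positions, dtype=int)
    M, valid = _contribution_matrices(profile, variants, positions)
    values = np.einsum("v,vic->ic", p, M)
    if not valid.all():
        warnings.warn("window extends beyond the calibrated profile; positions truncated", stacklevel=2)
    return ExpectedSignal(values=values, valid=valid, start=int(positions[0]) if len(positions) else 0)


@dataclass
class MixtureEstimate:
    """Best-fitting mixture proportions over a comparison window."""

    variants: LengthVariantSet
    proportions: dict[str, float]  # refined (sub-grid) fractions
    grid_proportions: dict[str, float]
    objective: float
    window: tuple[int, int]
    grid_step: float
    n_positions: int
    window_flagged: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def percentages(self) -> dict[str, float]:
        return {lab: round(100.0 * f, 2) for lab, f in self.proportions.items()}


def _simplex_grid(k: int, n_steps: int) -> np.ndarray:
    """All k-part compositions of n_steps, as fractions (rows sum to 1)."""
    combos = itertools.combinations(range(n_steps + k - 1), k - 1)
    out = np.empty((0, k))
    rows = []
    for dividers in combos:
        prev = -1
        parts = []
        for d in dividers:
            parts.append(d - prev - 1)
            prev = d
        parts.append(n_steps + k - 2 - prev)
        rows.append(parts)
    out = np.asarray(rows, dtype=float) / n_steps if rows else np.zeros((1, k))
    return out


def _local_grid(center: np.ndarray, k: int, n_steps: int, radius: int) -> np.ndarray:
    """Fine-grid compositions of n_steps within `radius` steps of `center` counts."""
    c = np.round(center * n_steps).astype(int)
    ranges = [range(max(0, ci - radius), min(n_steps, ci + radius) + 1) for ci in c]
    rows = [t for t in itertools.product(*ranges[:-1]) if 0 <= n_steps - sum(t) <= n_steps]
    grid = []
    for t in rows:
        last = n_steps - sum(t)
        if abs(last - c[-1]) <= radius:
            grid.append(t + (last,))
    return np.asarray(grid, dtype=float) / n_steps


def fit_proportions(
    observed: NormalizedSignals,
    profile: IntrinsicProfile,
    variants: LengthVariantSet,
    window: tuple[int, int] | None = None,
    grid_step: float = 0.01,
    min_window: int = DEFAULT_MIN_WINDOW,
    objective_mode: str = "per_base",
    refine: bool = True,
    guard: int = 3,
) -> MixtureEstimate:
    """Grid-search the mixture proportions that best explain a direct read.

    The window starts at the indel site and spans `min_window` (200)
    positions, truncated (and flagged) at the read/profile end; fewer than
    50 usable positions is refused.  Positions inside the variable track and
    within `guard` positions after it are excluded: there the preceding
    sequence context differs between variants, so the shifted-profile
    superposition is not a valid expectation.  The objective is the sum of
    squared differences between observed and simulated intensities, per
    (position, base) by default or on per-position sums with
    objective_mode='sums'; because both sides are normalized run-wise, a
    free global scale on the observed window is profiled out analytically.
    The search is exhaustive at `grid_step` (coarse 0.05 then local 0.01
    when more than 3 variants), ties broken toward fewer nonzero variants;
    a quadratic polish then refines the optimum between grid points.
    """
    if observed.read_type != "direct":
        raise ValueError("fit_proportions expects a normalized direct read")
    k = len(variants.variants)
    site = variants.site
    fit_start = site.start + site.length + max(0, max(variants.shifts)) + guard
    if window is None:
        window = (site.start, min(fit_start + min_window, len(observed), len(profile)))
    lo, hi = window
    lo = max(lo, fit_start)
    flagged = (hi - lo) < min_window
    positions = np.arange(lo, min(hi, len(observed)))
    M, valid = _contribution_matrices(profile, variants, positions)
    positions = positions[valid]
    M = M[:, valid, :]
    if len(positions) < HARD_MIN_WINDOW:
        raise ValueError(
            f"only {len(positions)} usable window positions (need >= {HARD_MIN_WINDOW})"
        )
    obs = observed.values[positions]
    if not np.any(obs > 0):
        raise ValueError("observed window signal is all zero")
    if objective_mode == "sums":
        Mf = M.sum(axis=2)
        obs_f = obs.sum(axis=1)
    elif objective_mode == "per_base":
        Mf = M.reshape(k, -1)
        obs_f = obs.reshape(-1)
    else:
        raise ValueError(f"unknown objective_mode {objective_mode!r}")
    # residual after profiling out a global scale on the observed window:
    # obj(p) = ||Mp||^2 - (o . Mp)^2 / ||o||^2, quadratic-over-quadratic in p
    G = Mf @ Mf.T
    b = Mf @ obs_f
    S = float(obs_f @ obs_f)

    def batch_obj(P: np.ndarray) -> np.ndarray:
        return np.einsum("ij,jk,ik->i", P, G, P) - (P @ b) ** 2 / S

    if k > 3:
        coarse = _simplex_grid(k, round(1 / 0.05))
        inc = coarse[int(np.argmin(batch_obj(coarse)))]
        grid = _local_grid(inc, k, round(1 / grid_step), radius=round(0.05 / grid_step))
    else:
        grid = _simplex_grid(k, round(1 / grid_step))
    objs = batch_obj(grid)
    best = float(objs.min())
    tol = max(best * 1e-9, S * 1e-12)
    tied = grid[objs <= best + tol]
    order = sorted(
        range(len(tied)),
        key=lambda i: (int(np.count_nonzero(tied[i])), tuple(-tied[i])),
    )
    p_grid = tied[order[0]]

    p_ref = p_grid
    if refine:
        res = minimize(
            lambda p: float(p @ G @ p - (b @ p) ** 2 / S),
            p_grid,
            jac=lambda p: 2 * (G @ p - (b @ p) / S * b),
            method="SLSQP",
            bounds=[(0.0, 1.0)] * k,
            constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1.0}],
            options={"maxiter": 200, "ftol": 1e-14},
        )
        if res.success and res.fun <= best + tol:
            p_ref = np.clip(res.x, 0.0, 1.0)
            p_ref = p_ref / p_ref.sum()
    labels = variants.labels
    return MixtureEstimate(
        variants=variants,
        proportions={lab: float(f) for lab, f in zip(labels, p_ref)},
        grid_proportions={lab: float(f) for lab, f in zip(labels, p_grid)},
        objective=float(max(batch_obj(p_ref[None, :])[0], 0.0)),
        window=(int(positions[0]), int(positions[-1]) + 1),
        grid_step=grid_step,
        n_positions=len(positions),
        window_flagged=flagged,
    )


def infer_joint_site_proportions(
    length_percentages: dict[int, float],
    measured_site_percentage: float,
) -> float:
    """Infer one site's per-site deletion percentage from the total-length
    distribution and the other site's directly measured percentage.

    With two single-nt deletion sites, the total deletion count per molecule
    is the sum of the two site indicators, so over the pool
    E[d1] + E[d2] = 2 P(L-2) + P(L-1); the unmeasured site follows exactly.
    The result is clamped to [0, 100].
    """
    if not length_percentages:
        raise ValueError("empty length distribution")
    for L, pct in length_percentages.items():
        if not 0 <= pct <= 100:
            raise ValueError(f"percentage for length {L} outside [0, 100]: {pct}")
    if not 0 <= measured_site_percentage <= 100:
        raise ValueError(f"measured site percentage outside [0, 100]: {measured_site_percentage}")
    total = sum(length_percentages.values())
    if abs(total - 100) > 2:
        raise ValueError(f"length distribution sums to {total}, expected 100 +/- 2")
    L = max(length_percentages)
    if set(length_percentages) - {L, L - 1, L - 2}:
        raise ValueError("length distribution must cover at most {L, L-1, L-2}")
    p1 = length_percentages.get(L - 1, 0.0)
    p2 = length_percentages.get(L - 2, 0.0)
    other = 2.0 * p2 + p1 - measured_site_percentage
    return float(min(100.0, max(0.0, other)))
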