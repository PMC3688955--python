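"""Normalize runs to a common intensity scale and gate reads on noise quality.

Every sequencing run has its own overall signal level, so intensities are
rescaled so that the run mean equals 1000 units.  Clone reads are scaled on
the called-channel call-point values; direct (mixed-amplicon) reads are
scaled on per-position sums of the four channels' window maxima, because in
a mixture every channel may carry real signal at a position.  A read is
eligible for quantitative analysis only if, over a designated clean region,
off-channel signal stays below 10% of the called-channel signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trace_io import BASES, CallPointTable

TARGET_MEAN = 1000.0


class DegenerateSignalError(ValueError):
    """Raised when a read's mean intensity over the region is zero."""


@dataclass
class NormalizedSignals:
    """A call-point table scaled to the common 1000-unit level.

    values is (n_positions, 4) in base order A,C,G,T: scaled call-point
    intensities for clone reads, scaled window maxima for direct reads.
    position_sums is the per-position channel sum (direct reads only carry
    meaning; clone sums are computed the same way for convenience).
    """

    called_bases: list[str]
    values: np.ndarray
    position_sums: np.ndarray
    scale_factor: float
    read_type: str  # "clone" | "direct"
    region: tuple[int, int]  # 0-based half-open, in read coordinates
    sample_id: str = ""
    direction: str = "forward"
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.called_bases)

    @property
    def sequence(self) -> str:
        return "".join(self.called_bases)

    def called_channel_values(self) -> np.ndarray:
        out = np.full(len(self), np.nan)
        for i, b in enumerate(self.called_bases):
            if b in "ACGT":
                out[i] = self.values[i, BASES.index(b)]
        return out


def _check_region(table: CallPointTable, region: tuple[int, int], min_len: int = 30) -> None:
    lo, hi = region
    if not (0 <= lo < hi <= len(table)):
        raise ValueError(f"region {region} outside read of length {len(table)}")
    if hi - lo < min_len:
        raise ValueError(f"region {region} shorter than {min_len} positions")


def _called_mask(called_bases: list[str]) -> np.ndarray:
    # N calls carry no channel assignment; excluded from scaling statistics
    return np.array([b in "ACGT" for b in called_bases])


def normalize_clone_read(table: CallPointTable, region: tuple[int, int]) -> NormalizedSignals:
    """Scale a clone read so the called-channel mean over `region` is 1000.

    The same factor is applied to every channel at every position, so
    relative peak heights are untouched.
    """
    _check_region(table, region)
    lo, hi = region
    called = table.called_channel_values("point")
    mask = _called_mask(table.called_bases)
    sel = called[lo:hi][mask[lo:hi]]
    mean = float(np.mean(sel)) if sel.size else 0.0
    if mean <= 0:
        raise DegenerateSignalError("zero mean called-channel intensity over region")
    k = TARGET_MEAN / mean
    values = table.point * k
    return NormalizedSignals(
        called_bases=list(table.called_bases),
        values=values,
        position_sums=values.sum(axis=1),
        scale_factor=k,
        read_type="clone",
        region=region,
        sample_id=table.sample_id,
        direction=table.direction,
    )


def normalize_direct_read(table: CallPointTable, region: tuple[int, int]) -> NormalizedSignals:
    """Scale a direct read so the mean per-position channel sum over `region` is 1000.

    Sums are built from window maxima: minor-variant peaks do not always sit
    exactly on the call point, so the window maximum is the honest estimate
    of each channel's contribution at a position.
    """
    _check_region(table, region)
    lo, hi = region
    sums = table.window.sum(axis=1)
    mean = float(np.mean(sums[lo:hi]))
    if mean <= 0:
        raise DegenerateSignalError("zero mean position sum over region")
    k = TARGET_MEAN / mean
    values = table.window * k
    return NormalizedSignals(
        called_bases=list(table.called_bases),
        values=values,
        position_sums=values.sum(axis=1),
        scale_factor=k,
        read_type="direct",
        region=region,
        sample_id=table.sample_id,
        direction=table.direction,
    )


@dataclass
class NoiseReport:
    noise_fraction: float
    clean_region: tuple[int, int]
    threshold: float
    passed: bool


def assess_noise(
    table: CallPointTable,
    clean_region: tuple[int, int],
    threshold: float = 0.10,
) -> NoiseReport:
    """Estimate baseline noise over a region known to be homogeneous.

    noise_fraction is the mean (over clean positions) of the largest
    non-called channel's window intensity, divided by the mean called-channel
    intensity; the max of the three off channels is a conservative choice.
    Reads with noise_fraction above the threshold (default 10%) are not
    eligible for quantitative analysis.
    """
    lo, hi = clean_region
    if hi <= lo:
        raise ValueError("empty clean region")
    _check_region(table, clean_region, min_len=1)
    mask = _called_mask(table.called_bases)[lo:hi]
    if not mask.any():
        raise ValueError("clean region contains no A/C/G/T calls")
    window = table.window[lo:hi][mask]
    called_idx = np.array([BASES.index(b) for b in table.called_bases[lo:hi] if b in "ACGT"])
    rows = np.arange(len(called_idx))
    called_vals = window[rows, called_idx]
    off = window.copy()
    off[rows, called_idx] = -np.inf
    off_max = off.max(axis=1)
    mean_called = float(called_vals.mean())
    if mean_called <= 0:
        raise DegenerateSignalError("zero called-channel signal in clean region")
    frac = float(off_max.mean()) / mean_called
    return NoiseReport(
        noise_fraction=frac,
        clean_region=clean_region,
        threshold=threshold,
        passed=frac <= threshold,
    )
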