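"""Learn expected (intrinsic) per-position signal intensities from clone reads.

The intensity a Sanger sequencer registers for a base depends on the bases
preceding it, so every position in a sequence has a repeatable, characteristic
peak height.  Sequencing a set of clones of (nearly) the same amplicon and
averaging their normalized called-channel intensities per aligned position
yields an intrinsic profile: the expected signal for each mainly represented
nucleotide at each position, with its across-clone standard deviation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signal_prep import NormalizedSignals


class CloneOutlierError(ValueError):
    """Raised when a clone diverges from the reference by more than 5%."""


@dataclass
class IndelSite:
    """A homopolymer track in the reference where length variants may differ.

    start/end are 0-based half-open reference coordinates of the maximal run.
    """

    start: int
    end: int
    base: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CloneAlignment:
    """Clone sequences laid out over reference coordinates.

    For each clone: a gapped sequence (``-`` at deleted reference positions)
    and a map ref_pos -> clone read position (-1 at gaps).  Gaps are confined
    to the declared homopolymer tracks and canonically placed at the 3' end
    of each track.  Columns where a clone's base differs from the reference
    are recorded as substitution candidates.
    """

    reference: str
    clone_ids: list[str]
    gapped: list[str]
    ref_to_read: np.ndarray  # (n_clones, ref_len) int, -1 at gaps
    substitution_columns: dict[int, dict[str, str]] = field(default_factory=dict)


def _align_one(clone: str, reference: str, sites: list[IndelSite]) -> tuple[str, np.ndarray]:
    """Align one clone to the reference allowing indels only in declared tracks.

    Walks reference and clone in step; at each declared track the clone's run
    of the track base is measured and the length difference absorbed there
    (deletion gaps at the 3' end of the track; extra clone bases treated as
    insertions that shift all downstream read positions).
    """
    ref_len = len(reference)
    mapping = np.full(ref_len, -1, dtype=int)
    gapped = ["-"] * ref_len
    sites_sorted = sorted(sites, key=lambda s: s.start)
    r = 0  # reference cursor
    c = 0  # clone cursor
    for site in sites_sorted:
        # copy the invariant block before the track
        block = site.start - r
        if c + block > len(clone):
            block = len(clone) - c
        for j in range(block):
            mapping[r + j] = c + j
            gapped[r + j] = clone[c + j]
        r += block
        c += block
        # measure the clone's homopolymer run
        run = 0
        while c + run < len(clone) and clone[c + run] == site.base:
            run += 1
        keep = min(run, site.length)
        for j in range(keep):  # aligned track bases, 5' first
            mapping[site.start + j] = c + j
            gapped[site.start + j] = site.base
        # deletion: 3'-most track positions stay gapped; insertion: skip extras
        r = site.end
        c += run
    tail = min(ref_len - r, len(clone) - c)
    for j in range(tail):
        mapping[r + j] = c + j
        gapped[r + j] = clone[c + j]
    return "".join(gapped), mapping


def align_clones(
    clone_seqs: dict[str, str] | list[str],
    reference: str,
    indel_sites: list[IndelSite],
    max_divergence: float = 0.05,
) -> CloneAlignment:
    """Align clone sequences to the reference, gaps only at declared indel sites."""
    if isinstance(clone_seqs, list):
        clone_seqs = {f"clone{i}": s for i, s in enumerate(clone_seqs)}
    for site in indel_sites:
        track = reference[site.start : site.end]
        if track != site.base * site.length:
            raise ValueError(f"declared site {site} is not a {site.base}-track in the reference")
    clone_ids = list(clone_seqs)
    gapped_rows: list[str] = []
    maps = np.full((len(clone_ids), len(reference)), -1, dtype=int)
    subs: dict[int, dict[str, str]] = {}
    for row, cid in enumerate(clone_ids):
        gapped, mapping = _align_one(clone_seqs[cid], reference, indel_sites)
        aligned = sum(1 for g in gapped if g != "-")
        mismatches = sum(1 for g, rbase in zip(gapped, reference) if g not in ("-", rbase))
        if aligned == 0 or mismatches / aligned > max_divergence:
            raise CloneOutlierError(f"clone {cid!r} diverges from the reference by more than 5%")
        for pos, (g, rbase) in enumerate(zip(gapped, reference)):
            if g not in ("-", rbase):
                subs.setdefault(pos, {})[cid] = g
        gapped_rows.append(gapped)
        maps[row] = mapping
    return CloneAlignment(
        reference=reference,
        clone_ids=clone_ids,
        gapped=gapped_rows,
        ref_to_read=maps,
        substitution_columns=subs,
    )


@dataclass
class IntrinsicProfile:
    """Expected intensity of the mainly represented base at each reference position.

    Arrays are indexed by 0-based reference position; NaN where no clone
    covers the position.  sd is the population standard deviation.
    """

    reference: str
    expected: np.ndarray
    sd: np.ndarray
    n_clones: np.ndarray
    consensus: list[str]
    direction: str = "forward"
    min_clones_calibrated: int = 3
    # per (position, base) means for minority alleles at substitution columns
    allele_expected: dict[tuple[int, str], float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reference)

    @property
    def covered(self) -> np.ndarray:
        return self.n_clones > 0

    @property
    def calibrated(self) -> np.ndarray:
        return self.n_clones >= self.min_clones_calibrated

    def expected_for(self, pos: int, base: str) -> float:
        """Expected intensity of `base` at `pos`: allele-specific mean when
        clones carrying that base were sequenced, else the consensus value
        (channel equivalence assumed for rare alleles)."""
        if (pos, base) in self.allele_expected:
            return self.allele_expected[(pos, base)]
        return float(self.expected[pos])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("ref_pos\tbase\tmean\tsd\tn\n")
            for i in range(len(self)):
                if self.n_clones[i] == 0:
                    continue
                fh.write(
                    f"{i + 1}\t{self.consensus[i]}\t{self.expected[i]:.4f}"
                    f"\t{self.sd[i]:.4f}\t{int(self.n_clones[i])}\n"
                )


def build_intrinsic_profile(
    clone_reads: dict[str, NormalizedSignals] | list[NormalizedSignals],
    alignment: CloneAlignment,
    min_clones_calibrated: int = 3,
) -> IntrinsicProfile:
    """Average normalized clone intensities per aligned reference position.

    At positions where clones disagree on the base, only clones carrying the
    majority base contribute to the expected value; minority-allele means are
    kept separately for substitution quantification.
    """
    if isinstance(clone_reads, list):
        clone_reads = {cid: r for cid, r in zip(alignment.clone_ids, clone_reads)}
    missing = set(alignment.clone_ids) - set(clone_reads)
    if missing:
        raise ValueError(f"no normalized read for clones {sorted(missing)}")
    ref_len = len(alignment.reference)
    per_pos_values: list[dict[str, list[float]]] = [dict() for _ in range(ref_len)]
    direction = next(iter(clone_reads.values())).direction
    for row, cid in enumerate(alignment.clone_ids):
        read = clone_reads[cid]
        if read.read_type != "clone":
            raise ValueError(f"read for {cid!r} is not a normalized clone read")
        called = read.called_channel_values()
        for pos in range(ref_len):
            rp = alignment.ref_to_read[row, pos]
            if rp < 0 or rp >= len(read):
                continue
            base = alignment.gapped[row][pos]
            if base == "-" or read.called_bases[rp] != base:
                continue
            v = called[rp]
            if np.isfinite(v):
                per_pos_values[pos].setdefault(base, []).append(float(v))
    expected = np.full(ref_len, np.nan)
    sd = np.full(ref_len, np.nan)
    n_clones = np.zeros(ref_len, dtype=int)
    consensus = ["N"] * ref_len
    allele_expected: dict[tuple[int, str], float] = {}
    for pos, by_base in enumerate(per_pos_values):
        if not by_base:
            continue
        counts = Counter({b: len(v) for b, v in by_base.items()})
        major = max(sorted(counts), key=lambda b: counts[b])
        vals = np.asarray(by_base[major])
        expected[pos] = vals.mean()
        sd[pos] = vals.std()  # population SD
        n_clones[pos] = len(vals)
        consensus[pos] = major
        for base, v in by_base.items():
            allele_expected[(pos, base)] = float(np.mean(v))
    return IntrinsicProfile(
        reference=alignment.reference,
        expected=expected,
        sd=sd,
        n_clones=n_clones,
        consensus=consensus,
        direction=direction,
        min_clones_calibrated=min_clones_calibrated,
        allele_expected=allele_expected,
    )


@dataclass
class ProfileQC:
    mean_relative_sd: float
    n_covered: int
    n_calibrated: int
    flagged_positions: list[int]


def profile_qc(profile: IntrinsicProfile, flag_factor: float = 3.0) -> ProfileQC:
    """Summarize a profile: mean relative SD over covered positions, coverage,
    and positions whose relative SD exceeds `flag_factor` times the mean."""
    cov = profile.covered & (profile.expected > 0)
    if not cov.any():
        raise ValueError("profile covers no positions")
    rel = profile.sd[cov] / profile.expected[cov]
    mean_rel = float(rel.mean())
    flagged = []
    if mean_rel > 0:
        idx = np.flatnonzero(cov)
        flagged = [int(i) for i, r in zip(idx, rel) if r > flag_factor * mean_rel]
    return ProfileQC(
        mean_relative_sd=mean_rel,
        n_covered=int(cov.sum()),
        n_calibrated=int(profile.calibrated.sum()),
        flagged_positions=flagged,
    )
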