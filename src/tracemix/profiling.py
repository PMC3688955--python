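"""Annotate ITS regions, apply detection thresholds, assemble ITS profiles.

An individual's ITS profile is the table of length-variant percentages,
substitution percentages and per-site deletion percentages for ITS1 and
ITS2, after detection thresholds (5% for length variants, 10% for
substitutions) have been applied.  Profiles of different individuals are
compared feature by feature; specimens of the same strain are expected to
differ in few or no features.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

MOTIF_18S_END = "GATCATTA"
MOTIF_58S_START = "ACAACTTC"
MOTIF_58S_END = "TCTGAGCG"
MOTIF_28S_START = "CGCTGAAT"

LENGTH_THRESHOLD = 5.0  # percent
SUB_THRESHOLD = 10.0  # percent


class AnnotationError(ValueError):
    """Raised when a border motif is absent or duplicated in the amplicon."""


@dataclass
class RegionAnnotation:
    """0-based half-open coordinates of ITS1, 5.8S and ITS2 in the amplicon,
    exclusive of the flanking border motifs."""

    its1: tuple[int, int]
    r58s: tuple[int, int]
    its2: tuple[int, int]

    @property
    def its1_length(self) -> int:
        return self.its1[1] - self.its1[0]

    @property
    def its2_length(self) -> int:
        return self.its2[1] - self.its2[0]

    def to_amplicon(self, region: str, region_pos_1based: int) -> int:
        """Map a 1-based position within a region to a 0-based amplicon index."""
        start = {"ITS1": self.its1[0], "ITS2": self.its2[0], "5.8S": self.r58s[0]}[region]
        return start + region_pos_1based - 1


def _find_once(amplicon: str, motif: str) -> int:
    first = amplicon.find(motif)
    if first < 0:
        raise AnnotationError(f"border motif {motif} not found")
    if amplicon.find(motif, first + 1) >= 0:
        raise AnnotationError(f"border motif {motif} occurs more than once")
    return first


def locate_regions(amplicon: str) -> RegionAnnotation:
    """Annotate ITS1 and ITS2 by their conserved border motifs.

    ITS1 lies between the last 8 nt of 18S (GATCATTA) and the first 8 nt of
    5.8S (ACAACTTC); ITS2 between the end of 5.8S (TCTGAGCG) and the start
    of 28S (CGCTGAAT).  Each motif must occur exactly once, in order.
    """
    amplicon = amplicon.upper()
    p18 = _find_once(amplicon, MOTIF_18S_END)
    p58a = _find_once(amplicon, MOTIF_58S_START)
    p58b = _find_once(amplicon, MOTIF_58S_END)
    p28 = _find_once(amplicon, MOTIF_28S_START)
    if not p18 + len(MOTIF_18S_END) <= p58a < p58b + len(MOTIF_58S_END) <= p28:
        raise AnnotationError("border motifs are out of order")
    return RegionAnnotation(
        its1=(p18 + len(MOTIF_18S_END), p58a),
        r58s=(p58a, p58b + len(MOTIF_58S_END)),
        its2=(p58b + len(MOTIF_58S_END), p28),
    )


FeatureKey = tuple[str, str, object]  # (region, kind in {len, sub, del}, key)


@dataclass
class ITSProfile:
    """Per-individual ITS heterogeneity profile.

    length_pct:   region -> {region length (nt) -> percent}
    substitution_pct: region -> {(1-based position, base) -> percent}
    deletion_pct: region -> {1-based site position -> percent}
    """

    sample_id: str
    length_pct: dict[str, dict[int, float]] = field(default_factory=dict)
    substitution_pct: dict[str, dict[tuple[int, str], float]] = field(default_factory=dict)
    deletion_pct: dict[str, dict[int, float]] = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    thresholds_applied: bool = False

    def features(self) -> dict[FeatureKey, float]:
        out: dict[FeatureKey, float] = {}
        for region, d in self.length_pct.items():
            for length, pct in d.items():
                out[(region, "len", length)] = pct
        for region, d in self.substitution_pct.items():
            for key, pct in d.items():
                out[(region, "sub", key)] = pct
        for region, d in self.deletion_pct.items():
            for pos, pct in d.items():
                out[(region, "del", pos)] = pct
        return out


def apply_thresholds(
    profile: ITSProfile,
    length_threshold: float = LENGTH_THRESHOLD,
    substitution_threshold: float = SUB_THRESHOLD,
) -> ITSProfile:
    """Zero out length variants below 5% and drop substitutions below 10%.

    Surviving percentages are NOT renormalized: they are estimates, so
    region totals may fall short of 100.  Idempotent, and raising a
    threshold can only remove features.
    """
    lengths = {
        region: {L: (pct if pct >= length_threshold else 0.0) for L, pct in d.items()}
        for region, d in profile.length_pct.items()
    }
    subs = {
        region: {key: pct for key, pct in d.items() if pct >= substitution_threshold}
        for region, d in profile.substitution_pct.items()
    }
    dels = {
        region: {pos: (pct if pct >= length_threshold else 0.0) for pos, pct in d.items()}
        for region, d in profile.deletion_pct.items()
    }
    return ITSProfile(
        sample_id=profile.sample_id,
        length_pct=lengths,
        substitution_pct=subs,
        deletion_pct=dels,
        qc=dict(profile.qc),
        thresholds_applied=True,
    )


@dataclass
class ReplicateStats:
    values: list[float]
    reference_mean: float
    deviations: list[float]  # |value - reference mean| for every value

    def range_over(self, indices: list[int] | None = None) -> float:
        vals = self.values if indices is None else [self.values[i] for i in indices]
        if not vals:
            raise ValueError("empty subset")
        return max(vals) - min(vals)


def replicate_stats(values: list[float], reference_subset: list[int]) -> ReplicateStats:
    """Mean over a designated reference subset of replicate measurements and
    each value's absolute deviation from that mean."""
    if len(reference_subset) < 2:
        raise ValueError("reference subset needs at least 2 values")
    ref = [values[i] for i in reference_subset]
    mean = sum(ref) / len(ref)
    return ReplicateStats(
        values=list(values),
        reference_mean=mean,
        deviations=[abs(v - mean) for v in values],
    )


def count_distinguishing_features(
    a: ITSProfile,
    b: ITSProfile,
    criterion: str = "any",
    length_margin: float = 5.0,
    substitution_margin: float = 10.0,
) -> int:
    """Number of profile features whose (thresholded) values differ.

    criterion 'any': any nonzero difference counts.  criterion 'margin':
    a feature counts only when the difference exceeds the permitted error
    (5 points for length-type features, 10 for substitutions), which
    discounts replicate-level scatter between same-strain specimens.
    Symmetric, and 0 for identical profiles.
    """
    fa, fb = a.features(), b.features()
    count = 0
    for key in sorted(set(fa) | set(fb), key=repr):
        va = fa.get(key, 0.0)
        vb = fb.get(key, 0.0)
        diff = abs(va - vb)
        if criterion == "any":
            if diff > 0:
                count += 1
        elif criterion == "margin":
            margin = substitution_margin if key[1] == "sub" else length_margin
            if diff > margin:
                count += 1
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
    return count


def distinguishing_features(
    a: ITSProfile, b: ITSProfile, criterion: str = "any", **margins
) -> list[FeatureKey]:
    """The differing feature keys themselves (same rules as the count)."""
    fa, fb = a.features(), b.features()
    out = []
    for key in sorted(set(fa) | set(fb), key=repr):
        diff = abs(fa.get(key, 0.0) - fb.get(key, 0.0))
        if criterion == "any" and diff > 0:
            out.append(key)
        elif criterion == "margin":
            margin = margins.get(
                "substitution_margin" if key[1] == "sub" else "length_margin",
                10.0 if key[1] == "sub" else 5.0,
            )
            if diff > margin:
                out.append(key)
    return out


@dataclass
class ProfileComparison:
    """Feature-aligned comparison across a set of profiles."""

    sample_ids: list[str]
    feature_keys: list[FeatureKey]
    table: dict[FeatureKey, list[float]]
    criterion: str = "any"

    def count(self, sample_a: str, sample_b: str) -> int:
        ia, ib = self.sample_ids.index(sample_a), self.sample_ids.index(sample_b)
        n = 0
        for key in self.feature_keys:
            if abs(self.table[key][ia] - self.table[key][ib]) > 0:
                n += 1
        return n

    def feature_range(self, key: FeatureKey) -> float:
        vals = self.table[key]
        return max(vals) - min(vals)


def compare_profiles(profiles: list[ITSProfile]) -> ProfileComparison:
    feats = [p.features() for p in profiles]
    keys = sorted({k for f in feats for k in f}, key=repr)
    return ProfileComparison(
        sample_ids=[p.sample_id for p in profiles],
        feature_keys=keys,
        table={k: [f.get(k, 0.0) for f in feats] for k in keys},
    )


def _feature_column(key: FeatureKey) -> str:
    region, kind, k = key
    if kind == "len":
        return f"{region}_len_{k}"
    if kind == "sub":
        pos, base = k
        return f"{region}_sub_{pos}{base}"
    return f"{region}_del_{k}"


def _parse_column(col: str) -> FeatureKey:
    region, kind, rest = col.split("_", 2)
    if kind == "len":
        return (region, "len", int(rest))
    if kind == "sub":
        return (region, "sub", (int(rest[:-1]), rest[-1]))
    if kind == "del":
        return (region, "del", int(rest))
    raise ValueError(f"unrecognized profile column {col!r}")


def profiles_to_tsv(profiles: list[ITSProfile], path: str | Path) -> None:
    keys = sorted({k for p in profiles for k in p.features()}, key=repr)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id"] + [_feature_column(k) for k in keys])
        for p in profiles:
            f = p.features()
            w.writerow([p.sample_id] + [format(f.get(k, 0.0), "g") for k in keys])


def profiles_from_tsv(path: str | Path) -> list[ITSProfile]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    out = []
    for row in rows:
        prof = ITSProfile(sample_id=row["sample_id"], thresholds_applied=True)
        for col, val in row.items():
            if col == "sample_id" or val in (None, ""):
                continue
            region, kind, key = _parse_column(col)
            pct = float(val)
            if kind == "len":
                prof.length_pct.setdefault(region, {})[key] = pct
            elif kind == "sub":
                if pct > 0:
                    prof.substitution_pct.setdefault(region, {})[key] = pct
            else:
                prof.deletion_pct.setdefault(region, {})[key] = pct
        out.append(prof)
    return out


def profile_to_json(profile: ITSProfile, path: str | Path) -> None:
    doc = {
        "sample_id": profile.sample_id,
        "length_pct": {r: {str(k): v for k, v in d.items()} for r, d in profile.length_pct.items()},
        "substitution_pct": {
            r: {f"{pos}{base}": v for (pos, base), v in d.items()}
            for r, d in profile.substitution_pct.items()
        },
        "deletion_pct": {r: {str(k): v for k, v in d.items()} for r, d in profile.deletion_pct.items()},
        "qc": profile.qc,
        "thresholds_applied": profile.thresholds_applied,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
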