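"""Synthetic chromatograms with known ground truth.

The generator emulates the statistical structure the proportion model relies
on, without modelling dye chemistry: every base has a repeatable intensity
determined by the k bases preceding it (a deterministic context model), runs
differ by a global gain, individual peak heights scatter multiplicatively by
about 5%, and off-channel baseline noise sits a configurable fraction below
or above the 10% QC bar.  Mixtures of length variants in homopolymer
T-tracks and substitution mixtures at defined positions are superposed
exactly as co-migrating templates superpose in a real direct read.

Everything is deterministic under a fixed seed, and every generated dataset
can be written to the tabular trace dialect (plus a minimal ABIF writer for
round-trip tests of the AB1 reader).
"""

from __future__ import annotations

import hashlib
import json
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .intrinsic import IndelSite
from .profiling import (
    MOTIF_18S_END,
    MOTIF_28S_START,
    MOTIF_58S_END,
    MOTIF_58S_START,
    RegionAnnotation,
    locate_regions,
)
from .trace_io import BASES, CallPointTable, Chromatogram

_REVCOMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


@dataclass(frozen=True)
class TrackSpec:
    """A homopolymer track: region, 1-based start within the region, length."""

    region: str
    start: int
    length: int
    base: str = "T"


@dataclass
class ReferenceSpec:
    """Region lengths and track placement of the synthetic amplicon.

    Defaults mirror the E. fluviatilis ITS amplicon: a 254-nt ITS1 with a
    3-nt T-track at positions 177-179, and a 323-nt ITS2 with T-tracks at
    10-13 and 246-247.
    """

    its1_length: int = 254
    its2_length: int = 323
    r58s_length: int = 157  # includes both border motifs
    tail18s_length: int = 40  # includes the terminal GATCATTA
    head28s_length: int = 220  # includes the leading CGCTGAAT
    tracks: tuple[TrackSpec, ...] = (
        TrackSpec("ITS1", 177, 3),
        TrackSpec("ITS2", 10, 4),
        TrackSpec("ITS2", 246, 2),
    )


@dataclass
class GeneratorConfig:
    seed: int = 0
    reference: ReferenceSpec = field(default_factory=ReferenceSpec)
    context_k: int = 3
    position_noise_sd: float = 0.05  # multiplicative lognormal scatter per peak
    baseline_noise: float = 0.02  # off-channel fraction of the position total
    offpoint_attenuation: float = 0.2  # minor-peak call-point deficit vs window max
    n_clones: int = 48


@dataclass
class Reference:
    """A synthetic amplicon with its annotation truth and absolute track sites."""

    amplicon: str
    annotation: RegionAnnotation
    sites: list[IndelSite]  # absolute 0-based coordinates, ordered
    spec: ReferenceSpec

    @property
    def length(self) -> int:
        return len(self.amplicon)

    def site_for(self, track: TrackSpec) -> IndelSite:
        start = self.annotation.to_amplicon(track.region, track.start)
        for s in self.sites:
            if s.start == start:
                return s
        raise KeyError(track)

    def sites_in_region(self, region: str) -> list[IndelSite]:
        lo, hi = {"ITS1": self.annotation.its1, "ITS2": self.annotation.its2}[region]
        return [s for s in self.sites if lo <= s.start < hi]

    def site_for_region(self, region: str) -> IndelSite:
        sites = self.sites_in_region(region)
        if len(sites) != 1:
            raise ValueError(f"{region} has {len(sites)} declared sites, expected 1")
        return sites[0]

    def its2_sites_near_far(self) -> tuple[IndelSite, IndelSite]:
        """ITS2 sites ordered (nearest to the reverse primer, farthest), i.e.
        (highest forward coordinate, lowest)."""
        sites = self.sites_in_region("ITS2")
        if len(sites) != 2:
            raise ValueError(f"ITS2 has {len(sites)} declared sites, expected 2")
        return sites[1], sites[0]


def _unit_hash(tag: str) -> float:
    """Deterministic value in [-1, 1) from a string tag."""
    h = hashlib.md5(tag.encode()).digest()
    return int.from_bytes(h[:8], "big") / 2.0**63 - 1.0


def context_intensity(kmer: str, base: str) -> float:
    """Deterministic intrinsic intensity for `base` preceded by `kmer`.

    The base itself sets the overall level; each preceding base modulates it
    multiplicatively with an influence that decays with distance (nearest
    neighbour strongest).  This reproduces position-specific repeatable peak
    heights, with nearby sequence mattering most, without a chemistry model.
    """
    val = 1000.0 * (1.0 + 0.25 * _unit_hash(f"B{base}"))
    weight = 0.18
    for prev in reversed(kmer):
        val *= 1.0 + weight * _unit_hash(f"{weight:.3f}:{prev}>{base}")
        weight *= 0.5
    return val


def _random_region(rng: np.random.Generator, length: int, forbid_base: str | None = None) -> list[str]:
    return [BASES[i] for i in rng.integers(0, 4, size=length)]


def make_reference(config: GeneratorConfig) -> Reference:
    """Build the synthetic amplicon with border motifs and homopolymer tracks.

    Filler sequence is random under the seed; tracks are placed verbatim with
    non-track flanking bases so each declared site is a maximal run, and the
    construction is retried until every border motif occurs exactly once.
    """
    spec = config.reference
    rng = np.random.default_rng(config.seed)
    for motif, need in (
        (MOTIF_18S_END, spec.tail18s_length),
        (MOTIF_58S_START, spec.r58s_length - len(MOTIF_58S_END)),
        (MOTIF_28S_START, spec.head28s_length),
    ):
        if need < len(motif):
            raise ValueError(f"region too short to hold border motif {motif}")
    region_len = {"ITS1": spec.its1_length, "ITS2": spec.its2_length}
    for tr in spec.tracks:
        if tr.start < 2 or tr.start + tr.length - 1 >= region_len[tr.region]:
            raise ValueError(f"track {tr} does not fit inside {tr.region}")
    for _attempt in range(64):
        regions: dict[str, list[str]] = {
            "ITS1": _random_region(rng, spec.its1_length),
            "ITS2": _random_region(rng, spec.its2_length),
        }
        for tr in spec.tracks:
            seq = regions[tr.region]
            s0 = tr.start - 1
            for j in range(tr.length):
                seq[s0 + j] = tr.base
            # maximal run: flanks must not extend the track
            others = [b for b in BASES if b != tr.base]
            if s0 > 0 and seq[s0 - 1] == tr.base:
                seq[s0 - 1] = others[int(rng.integers(0, 3))]
            if s0 + tr.length < len(seq) and seq[s0 + tr.length] == tr.base:
                seq[s0 + tr.length] = others[int(rng.integers(0, 3))]
        tail = _random_region(rng, spec.tail18s_length - len(MOTIF_18S_END))
        mid = _random_region(rng, spec.r58s_length - len(MOTIF_58S_START) - len(MOTIF_58S_END))
        head = _random_region(rng, spec.head28s_length - len(MOTIF_28S_START))
        amplicon = "".join(
            [
                "".join(tail),
                MOTIF_18S_END,
                "".join(regions["ITS1"]),
                MOTIF_58S_START,
                "".join(mid),
                MOTIF_58S_END,
                "".join(regions["ITS2"]),
                MOTIF_28S_START,
                "".join(head),
            ]
        )
        try:
            ann = locate_regions(amplicon)
        except ValueError:
            continue
        if (ann.its1_length, ann.its2_length) != (spec.its1_length, spec.its2_length):
            continue
        sites = []
        ok = True
        for tr in spec.tracks:
            start = ann.to_amplicon(tr.region, tr.start)
            end = start + tr.length
            if amplicon[start:end] != tr.base * tr.length:
                ok = False
                break
            sites.append(IndelSite(start=start, end=end, base=tr.base))
        if ok:
            return Reference(amplicon=amplicon, annotation=ann, sites=sorted(sites, key=lambda s: s.start), spec=spec)
    raise RuntimeError("could not place border motifs uniquely; adjust the reference spec")


@dataclass
class Variant:
    """A template variant: sequence plus a map read position -> reference position."""

    seq: str
    ref_map: np.ndarray  # (len(seq),) int, -1 where no reference counterpart
    shifts: dict[int, int]  # site index -> shift

    @property
    def total_shift(self) -> int:
        return sum(self.shifts.values())


def make_variant(reference: Reference, shifts: dict[int, int]) -> Variant:
    """Apply per-site track shifts (deletion < 0) to the reference amplicon.

    Deleted bases are removed from the 3' end of each track; inserted track
    bases are added there.
    """
    seq: list[str] = []
    ref_map: list[int] = []
    prev = 0
    for idx, site in enumerate(reference.sites):
        s = shifts.get(idx, 0)
        if site.length + s < 0:
            raise ValueError(f"shift {s} exceeds track length {site.length}")
        for pos in range(prev, site.start):
            seq.append(reference.amplicon[pos])
            ref_map.append(pos)
        new_len = site.length + s
        for j in range(new_len):
            seq.append(site.base)
            ref_map.append(site.start + min(j, site.length - 1))
        prev = site.end
    for pos in range(prev, reference.length):
        seq.append(reference.amplicon[pos])
        ref_map.append(pos)
    return Variant(seq="".join(seq), ref_map=np.asarray(ref_map), shifts=dict(shifts))


def _read_frame(variant: Variant, direction: str, ref_length: int) -> Variant:
    """Express a variant in its read frame: identity for forward reads,
    reverse-complement (with the map recast onto the reverse-complemented
    reference's coordinates) for reverse reads."""
    if direction == "forward":
        return variant
    seq = revcomp(variant.seq)
    m = variant.ref_map[::-1].copy()
    valid = m >= 0
    m[valid] = ref_length - 1 - m[valid]
    return Variant(seq=seq, ref_map=m, shifts=dict(variant.shifts))


def reference_in_read_frame(reference: Reference, direction: str) -> str:
    return reference.amplicon if direction == "forward" else revcomp(reference.amplicon)


def site_in_read_frame(site: IndelSite, direction: str, ref_length: int) -> IndelSite:
    if direction == "forward":
        return site
    return IndelSite(
        start=ref_length - site.end,
        end=ref_length - site.start,
        base=site.base.translate(_REVCOMP),
    )


def _called_series(seq: str, cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    k = cfg.context_k
    out = np.empty(len(seq))
    for i, base in enumerate(seq):
        kmer = seq[max(0, i - k) : i]
        out[i] = context_intensity(kmer, base)
    if cfg.position_noise_sd > 0:
        out *= np.exp(rng.normal(0.0, cfg.position_noise_sd, size=len(seq)))
    return out


def _finish_table(
    values: np.ndarray,
    called_bases: list[str],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    direction: str,
    sample_id: str,
) -> CallPointTable:
    n = len(called_bases)
    window = values.copy()
    if cfg.baseline_noise > 0:
        totals = window.sum(axis=1, keepdims=True)
        window += cfg.baseline_noise * totals * rng.uniform(0.5, 1.5, size=(n, 4))
    point = window.copy()
    if cfg.offpoint_attenuation > 0:
        # minor peaks need not crest exactly at the call point
        att = 1.0 - cfg.offpoint_attenuation * rng.uniform(0.0, 1.0, size=(n, 4))
        called_idx = np.array([BASES.index(b) for b in called_bases])
        att[np.arange(n), called_idx] = 1.0
        point = window * att
    return CallPointTable(
        called_bases=called_bases,
        point=point,
        window=window,
        direction=direction,
        sample_id=sample_id,
    )


def simulate_clone_read(
    seq: str,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    direction: str = "forward",
    sample_id: str = "clone",
) -> CallPointTable:
    """One clone read of a single template: context intensity x lognormal noise
    on the called channel, baseline on the others."""
    read_seq = seq if direction == "forward" else revcomp(seq)
    called = _called_series(read_seq, cfg, rng)
    values = np.zeros((len(read_seq), 4))
    for i, base in enumerate(read_seq):
        values[i, BASES.index(base)] = called[i]
    return _finish_table(values, list(read_seq), cfg, rng, direction, sample_id)


@dataclass(frozen=True)
class SubstitutionSpec:
    """A substitution mixture truth at a reference amplicon position (0-based,
    forward frame): `fraction` of all molecules carry `alt` instead of the
    reference base."""

    position: int
    alt: str
    fraction: float


def simulate_direct_read(
    reference: Reference,
    components: list[tuple[dict[int, int], float]],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    direction: str = "forward",
    substitutions: list[SubstitutionSpec] = (),
    sample_id: str = "direct",
) -> CallPointTable:
    """A direct read of a mixture: proportion-weighted superposition of the
    component variants' clone-model signals, with substitution truths
    splitting the called channel at their positions."""
    props = np.array([p for _, p in components], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"component proportions must sum to 1, got {props.sum()}")
    ref_len = reference.length
    subs_by_refpos: dict[int, SubstitutionSpec] = {}
    for sub in substitutions:
        pos, alt = sub.position, sub.alt
        if direction == "reverse":
            pos = ref_len - 1 - pos
            alt = alt.translate(_REVCOMP)
        subs_by_refpos[pos] = replace(sub, position=pos, alt=alt)
    frames = [
        _read_frame(make_variant(reference, shifts), direction, ref_len)
        for shifts, _ in components
    ]
    n = max(len(v.seq) for v in frames)
    values = np.zeros((n, 4))
    k = cfg.context_k
    for var, p in zip(frames, props):
        called = _called_series(var.seq, cfg, rng)
        for i, base in enumerate(var.seq):
            refpos = int(var.ref_map[i])
            sub = subs_by_refpos.get(refpos)
            if sub is not None and sub.alt != base:
                kmer = var.seq[max(0, i - k) : i]
                alt_val = context_intensity(kmer, sub.alt)
                if cfg.position_noise_sd > 0:
                    alt_val *= np.exp(rng.normal(0.0, cfg.position_noise_sd))
                values[i, BASES.index(base)] += p * (1.0 - sub.fraction) * called[i]
                values[i, BASES.index(sub.alt)] += p * sub.fraction * alt_val
            else:
                values[i, BASES.index(base)] += p * called[i]
    called_bases = [BASES[int(j)] for j in values.argmax(axis=1)]
    return _finish_table(values, called_bases, cfg, rng, direction, sample_id)


def clone_set(
    reference: Reference,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    direction: str = "forward",
    shifts: dict[int, int] | None = None,
) -> dict[str, CallPointTable]:
    """n_clones replicate clone reads of one template (default: the reference)."""
    var = _read_frame(make_variant(reference, shifts or {}), direction, reference.length)
    return {
        f"clone{i:02d}": simulate_clone_read(
            var.seq, cfg, rng, direction="forward", sample_id=f"clone{i:02d}"
        )
        for i in range(cfg.n_clones)
    }


# ---------------------------------------------------------------------------
# On-disk artifacts


def table_to_chromatogram(
    table: CallPointTable, spacing: int = 6, sample_id: str | None = None
) -> Chromatogram:
    """Render a call-point table as a scan-level chromatogram.

    Call points sit `spacing` scans apart; each channel's window maximum is
    placed one scan off the call point when it exceeds the call-point value,
    so extract_call_points with the default 5-scan window recovers the table.
    """
    n = len(table)
    n_scans = spacing * n + spacing
    channels = np.zeros((4, n_scans))
    call_scans = np.arange(n) * spacing + spacing // 2
    for i, scan in enumerate(call_scans):
        channels[:, scan] = table.point[i]
        off = table.window[i] > table.point[i]
        channels[off, scan + 1] = table.window[i][off]
    return Chromatogram(
        sample_id=sample_id if sample_id is not None else table.sample_id,
        primer_name=table.primer_name,
        direction=table.direction,
        channels=channels,
        called_bases=list(table.called_bases),
        call_scans=call_scans,
    )


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def write_tabular_dataset(
    outdir: str | Path,
    cfg: GeneratorConfig,
    sample_id: str = "SYN1",
    its1_proportions: dict[int, float] | None = None,
    its1_sub: tuple[int, str, float] | None = (169, "A", 0.35),
    its2_state_proportions: dict[tuple[int, int], float] | None = None,
    variant_clone_fraction: float = 1 / 3,
) -> dict:
    """Write a complete synthetic study to `outdir` and return its truth.

    Contents: reference FASTA, clone and direct reads in the tabular trace
    dialect, a run manifest, a profiling config, and a truth manifest (JSON)
    so tests never re-derive ground truth from filenames.

    Defaults mimic a V2-like specimen: ITS1 lengths 253/254 at 25/75 with a
    35% A substitution at ITS1 position 169, and ITS2 deletion states over
    (site-13 shift, site-247 shift) giving 32%/33% per-site deletions.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    reference = make_reference(cfg)
    ann = reference.annotation
    if its1_proportions is None:
        its1_proportions = {253: 0.25, 254: 0.75}
    if its2_state_proportions is None:
        its2_state_proportions = {(-1, -1): 0.20, (-1, 0): 0.12, (0, -1): 0.13, (0, 0): 0.55}
    site_idx = {s.start: i for i, s in enumerate(reference.sites)}
    its1_site = reference.site_for_region("ITS1")
    far_site, near_site = reference.sites_in_region("ITS2")
    i_its1, i_far, i_near = (site_idx[s.start] for s in (its1_site, far_site, near_site))

    subs: list[SubstitutionSpec] = []
    truth_subs = []
    if its1_sub is not None:
        pos1, alt, frac = its1_sub
        subs.append(SubstitutionSpec(position=ann.to_amplicon("ITS1", pos1), alt=alt, fraction=frac))
        truth_subs.append({"region": "ITS1", "position": pos1, "alt": alt, "fraction": frac})

    manifest_rows = []
    # clone reads: a fraction of clones carries the substitution allele so the
    # intrinsic profile learns allele-specific expectations
    for direction in ("forward", "reverse"):
        n_variant = int(round(cfg.n_clones * variant_clone_fraction)) if subs else 0
        for i in range(cfg.n_clones):
            template = reference.amplicon
            if i < n_variant:
                t = list(template)
                for sub in subs:
                    t[sub.position] = sub.alt
                template = "".join(t)
            name = f"clone_{direction[0]}{i:02d}.tsv"
            table = simulate_clone_read(template, cfg, rng, direction=direction, sample_id=f"clone{i:02d}")
            write_tabular_trace(table, outdir / name)
            manifest_rows.append((name, f"clone{i:02d}", "18Sfw" if direction == "forward" else "28S5rev", direction, "clone"))

    # ITS1 mixture is read with the forward primer
    its1_components = [
        ({i_its1: length - ann.its1_length}, p) for length, p in its1_proportions.items()
    ]
    fwd = simulate_direct_read(reference, its1_components, cfg, rng, direction="forward", substitutions=subs, sample_id=sample_id)
    write_tabular_trace(fwd, outdir / f"{sample_id}_fwd.tsv")
    manifest_rows.append((f"{sample_id}_fwd.tsv", sample_id, "18Sfw", "forward", "direct"))

    # ITS2 deletion states are read with the reverse primer
    its2_components = [
        ({i_far: s13, i_near: s247}, p) for (s13, s247), p in its2_state_proportions.items()
    ]
    rev = simulate_direct_read(reference, its2_components, cfg, rng, direction="reverse", sample_id=sample_id)
    write_tabular_trace(rev, outdir / f"{sample_id}_rev.tsv")
    manifest_rows.append((f"{sample_id}_rev.tsv", sample_id, "28S5rev", "reverse", "direct"))

    write_fasta({"reference": reference.amplicon}, outdir / "reference.fasta")
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("file\tsample_id\tprimer\tdirection\tread_type\n")
        for row in manifest_rows:
            fh.write("\t".join(row) + "\n")

    def _region_pos(site: IndelSite, region: str) -> tuple[int, int]:
        lo = {"ITS1": ann.its1[0], "ITS2": ann.its2[0]}[region]
        return site.start - lo + 1, site.length

    t1 = _region_pos(its1_site, "ITS1")
    tf = _region_pos(far_site, "ITS2")
    tn = _region_pos(near_site, "ITS2")
    config_lines = [
        "reference=reference.fasta",
        f"its1_track={t1[0]}:{t1[1]}",
        f"its2_track_far={tf[0]}:{tf[1]}",
        f"its2_track_near={tn[0]}:{tn[1]}",
        "max_indel=2",
        "clean_region_forward=5:50",
        "clean_region_reverse=5:50",
        "noise_threshold=0.10",
    ]
    if its1_sub is not None:
        config_lines.append(f"sub_clean=ITS1:{its1_sub[0]}:{its1_sub[1]}:{reference.amplicon[ann.to_amplicon('ITS1', its1_sub[0])]}")
    (outdir / "config.txt").write_text("\n".join(config_lines) + "\n")

    d13 = 100.0 * sum(p for (s13, _), p in its2_state_proportions.items() if s13 < 0)
    d247 = 100.0 * sum(p for (_, s247), p in its2_state_proportions.items() if s247 < 0)
    its2_lengths: dict[int, float] = {}
    for (s13, s247), p in its2_state_proportions.items():
        L = ann.its2_length + s13 + s247
        its2_lengths[L] = its2_lengths.get(L, 0.0) + 100.0 * p
    truth = {
        "sample_id": sample_id,
        "its1_length_pct": {str(k): 100.0 * v for k, v in its1_proportions.items()},
        "its2_length_pct": {str(k): v for k, v in sorted(its2_lengths.items())},
        "its2_deletion_pct": {"site13": d13, "site247": d247},
        "substitutions": truth_subs,
        "seed": cfg.seed,
        "noise_sd": cfg.position_noise_sd,
    }
    write_truth(truth, outdir / "truth.json")
    return truth


def write_tabular_trace(table: CallPointTable, path: str | Path, spacing: int = 6) -> None:
    """Render a call-point table to the scan-level tabular dialect."""
    from .trace_io import write_tabular

    write_tabular(table_to_chromatogram(table, spacing=spacing), path)


def write_ab1(chrom: Chromatogram, path: str | Path, dye_order: str = "GATC") -> None:
    """Write a minimal valid ABIF file (analysed channels DATA9-12, basecalls
    PBAS2, call points PLOC2, dye order FWO_1) readable by Biopython."""
    entries: list[tuple[str, int, int, int, int, bytes]] = []
    for i, base in enumerate(dye_order):
        chan = np.asarray(np.round(np.clip(chrom.channels[BASES.index(base)], 0, 32767)), dtype=">i2")
        entries.append(("DATA", 9 + i, 4, 2, len(chan), chan.tobytes()))
    seq = "".join(chrom.called_bases).encode()
    entries.append(("PBAS", 2, 2, 1, len(seq), seq))
    ploc = np.asarray(chrom.call_scans, dtype=">i2")
    entries.append(("PLOC", 2, 4, 2, len(ploc), ploc.tobytes()))
    entries.append(("FWO_", 1, 2, 1, 4, dye_order.encode()))

    body = b""
    dir_entries = b""
    data_offset = 128
    for name, number, etype, esize, nelem, data in entries:
        dsize = len(data)
        if dsize <= 4:
            dir_entries += (
                struct.pack(">4sIhhII", name.encode(), number, etype, esize, nelem, dsize)
                + data.ljust(4, b"\0")
                + b"\0" * 4
            )
        else:
            dir_entries += (
                struct.pack(
                    ">4sIhhIII", name.encode(), number, etype, esize, nelem, dsize, data_offset + len(body)
                )
                + b"\0" * 4
            )
            body += data
    dir_offset = data_offset + len(body)
    header = b"ABIF" + struct.pack(">h", 101)
    tdir = (
        struct.pack(">4sIhhIII", b"tdir", 1, 1023, 28, len(entries), len(entries) * 28, dir_offset)
        + b"\0" * 4
    )
    with open(path, "wb") as fh:
        fh.write(header + tdir + b"\0" * (128 - len(header) - len(tdir)))
        fh.write(body)
        fh.write(dir_entries)
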