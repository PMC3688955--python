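"""Read Sanger chromatograms and reduce them to per-basecall intensity tables.

Two on-disk forms are supported: standard ABIF (``.ab1``) files, parsed with
Biopython, and a plain tabular trace dialect (TSV with one row per scan point)
that is convenient for synthetic data and for values exported from trace
viewers.  Downstream analysis never touches scan-level traces: everything
operates on :class:`CallPointTable`, which records, for every basecall, the
intensity of each dye channel at the call point and the maximum of each
channel in a small scan window centred on the call point.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
# channel permutation under reverse-complement: A<->T, C<->G
_COMPLEMENT_PERM = np.array([3, 2, 1, 0])


class TraceFormatError(ValueError):
    """Raised when a chromatogram file is malformed or missing required fields."""


class EmptyReadError(ValueError):
    """Raised when a chromatogram contains no basecalls."""


@dataclass
class Chromatogram:
    """Raw four-channel trace with basecalls.

    channels has shape (4, n_scans) in the fixed base order A, C, G, T,
    regardless of the instrument's dye order. Basecall scan positions are
    strictly increasing indices into the scan axis.
    """

    sample_id: str
    primer_name: str
    direction: str  # "forward" | "reverse"
    channels: np.ndarray  # (4, n_scans) float
    called_bases: list[str]
    call_scans: np.ndarray  # (n_calls,) int

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        self.call_scans = np.asarray(self.call_scans, dtype=int)
        if self.channels.ndim != 2 or self.channels.shape[0] != 4:
            raise TraceFormatError("channels must be a (4, n_scans) array")
        if len(self.called_bases) == 0:
            raise EmptyReadError("chromatogram has zero basecalls")
        if len(self.called_bases) != len(self.call_scans):
            raise TraceFormatError("basecall and scan-position lengths differ")
        if np.any(np.diff(self.call_scans) <= 0):
            raise TraceFormatError("basecall scan positions must be strictly increasing")
        n = self.channels.shape[1]
        if self.call_scans[0] < 0 or self.call_scans[-1] >= n:
            raise TraceFormatError("basecall scan position outside trace range")
        bad = set(self.called_bases) - set("ACGTN")
        if bad:
            raise TraceFormatError(f"invalid called bases: {sorted(bad)}")


@dataclass
class CallPointTable:
    """Per-basecall per-channel intensities.

    point and window are (n_calls, 4) arrays in base order A, C, G, T;
    window[i, c] is the maximum of channel c over the scan window centred on
    basecall i's call point, so window >= point everywhere.
    """

    called_bases: list[str]
    point: np.ndarray
    window: np.ndarray
    direction: str = "forward"
    direction_normalized: bool = False
    sample_id: str = ""
    primer_name: str = ""
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.called_bases)

    @property
    def sequence(self) -> str:
        return "".join(self.called_bases)

    def called_channel_values(self, which: str = "point") -> np.ndarray:
        """Intensity of the called base's own channel at each position (NaN for N)."""
        arr = self.point if which == "point" else self.window
        out = np.full(len(self), np.nan)
        for i, b in enumerate(self.called_bases):
            if b in _BASE_INDEX:
                out[i] = arr[i, _BASE_INDEX[b]]
        return out


def read_chromatogram(
    path: str | Path,
    format: str = "tabular",
    sample_id: str = "",
    primer_name: str = "",
    direction: str = "forward",
) -> Chromatogram:
    """Read an AB1 or tabular trace file into a :class:`Chromatogram`.

    For AB1, the analysed channels (DATA9-12) are reordered into A,C,G,T
    using the instrument's dye-order tag (FWO_1), never assumed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tabular":
        return _read_tabular(path, sample_id, primer_name, direction)
    if format == "ab1":
        return _read_ab1(path, sample_id, primer_name, direction)
    raise ValueError(f"unknown chromatogram format: {format!r}")


def _read_tabular(path: Path, sample_id: str, primer_name: str, direction: str) -> Chromatogram:
    scans: list[int] = []
    calls: list[tuple[int, str]] = []
    values: list[list[float]] = []
    with open(path, newline="") as fh:
        rows = csv.reader((ln for ln in fh if not ln.startswith("#")), delimiter="\t")
        header = next(rows, None)
        if header is None or [h.strip() for h in header[:6]] != ["scan", "call", "A", "C", "G", "T"]:
            raise TraceFormatError(f"{path}: expected header 'scan call A C G T'")
        for row_i, row in enumerate(rows):
            if not row:
                continue
            try:
                scan = int(row[0])
                vals = [float(x) for x in row[2:6]]
            except (ValueError, IndexError) as exc:
                raise TraceFormatError(f"{path}: bad row {row_i + 2}: {row}") from exc
            if scans and scan <= scans[-1]:
                raise TraceFormatError(f"{path}: scan column not strictly increasing at row {row_i + 2}")
            scans.append(scan)
            call = row[1].strip()
            if call != ".":
                calls.append((len(scans) - 1, call.upper()))
            values.append(vals)
    if not values:
        raise TraceFormatError(f"{path}: no scan rows")
    if not calls:
        raise EmptyReadError(f"{path}: no basecalls")
    channels = np.asarray(values, dtype=float).T
    return Chromatogram(
        sample_id=sample_id,
        primer_name=primer_name,
        direction=direction,
        channels=channels,
        called_bases=[b for _, b in calls],
        call_scans=np.array([i for i, _ in calls]),
    )


def _read_ab1(path: Path, sample_id: str, primer_name: str, direction: str) -> Chromatogram:
    from Bio import SeqIO

    try:
        record = SeqIO.read(str(path), "abi")
    except Exception as exc:  # noqa: BLE001 - biopython raises bare exceptions
        raise TraceFormatError(f"{path}: not a readable ABIF file ({exc})") from exc
    raw = record.annotations.get("abif_raw", {})
    missing = [t for t in ("DATA9", "DATA10", "DATA11", "DATA12", "PLOC2", "FWO_1") if t not in raw]
    if missing:
        raise TraceFormatError(f"{path}: ABIF missing tags {missing}")
    dye_order = raw["FWO_1"]
    if isinstance(dye_order, bytes):
        dye_order = dye_order.decode()
    if sorted(dye_order) != ["A", "C", "G", "T"]:
        raise TraceFormatError(f"{path}: unexpected dye order {dye_order!r}")
    data = [np.asarray(raw[t], dtype=float) for t in ("DATA9", "DATA10", "DATA11", "DATA12")]
    channels = np.empty((4, len(data[0])))
    for chan, base in zip(data, dye_order):
        channels[_BASE_INDEX[base]] = chan
    call_scans = np.asarray(raw["PLOC2"], dtype=int)
    if len(call_scans) == 0:
        raise EmptyReadError(f"{path}: no basecalls")
    return Chromatogram(
        sample_id=sample_id,
        primer_name=primer_name,
        direction=direction,
        channels=channels,
        called_bases=list(str(record.seq)),
        call_scans=call_scans,
    )


def extract_call_points(chrom: Chromatogram, window: int = 5) -> CallPointTable:
    """Reduce a chromatogram to call-point and window-maximum intensities.

    window is an odd number of scan points centred on each basecall's call
    point (default 5, i.e. +/-2 scans), truncated at the trace ends. Window
    maxima matter for mixed direct reads, where minor peaks need not sit
    exactly on the call point.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    half = window // 2
    n_scans = chrom.channels.shape[1]
    point = chrom.channels[:, chrom.call_scans].T.copy()
    window_arr = np.empty_like(point)
    for i, scan in enumerate(chrom.call_scans):
        lo = max(0, scan - half)
        hi = min(n_scans, scan + half + 1)
        window_arr[i] = chrom.channels[:, lo:hi].max(axis=1)
    return CallPointTable(
        called_bases=list(chrom.called_bases),
        point=point,
        window=window_arr,
        direction=chrom.direction,
        direction_normalized=False,
        sample_id=chrom.sample_id,
        primer_name=chrom.primer_name,
    )


def orient_read(table: CallPointTable, direction: str | None = None) -> CallPointTable:
    """Map a call-point table onto the forward strand of the amplicon.

    Forward tables are returned unchanged (flag set). Reverse tables are
    position-reversed with channels and calls complemented, so the result
    reads 5'->3' on the forward strand. Applying the reverse transform twice
    restores the original table.
    """
    direction = direction or table.direction
    if direction == "forward":
        return replace(table, direction_normalized=True)
    if direction != "reverse":
        raise ValueError(f"direction must be 'forward' or 'reverse', got {direction!r}")
    return replace(
        table,
        called_bases=[_COMPLEMENT[b] for b in reversed(table.called_bases)],
        point=table.point[::-1][:, _COMPLEMENT_PERM].copy(),
        window=table.window[::-1][:, _COMPLEMENT_PERM].copy(),
        direction_normalized=not table.direction_normalized,
    )


def write_tabular(chrom: Chromatogram, path: str | Path) -> None:
    """Write a chromatogram in the tabular trace dialect (inverse of reading it)."""
    call_at = {int(s): b for s, b in zip(chrom.call_scans, chrom.called_bases)}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["scan", "call", "A", "C", "G", "T"])
        for scan in range(chrom.channels.shape[1]):
            w.writerow(
                [scan, call_at.get(scan, ".")]
                + [format(v, ".10g") for v in chrom.channels[:, scan]]
            )


def read_manifest(path: str | Path) -> list[dict]:
    """Read a run manifest TSV: file, sample_id, primer, direction, read_type."""
    required = {"file", "sample_id", "primer", "direction", "read_type"}
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    if rows and not required.issubset(rows[0]):
        raise TraceFormatError(f"manifest missing columns: {sorted(required - set(rows[0]))}")
    for row in rows:
        if row["direction"] not in ("forward", "reverse"):
            raise TraceFormatError(f"bad direction {row['direction']!r} in manifest")
        if row["read_type"] not in ("clone", "direct"):
            raise TraceFormatError(f"bad read_type {row['read_type']!r} in manifest")
    return rows
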