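"""Readers and writers for the standard formats touched by the pipeline.

Single molecules ("fibers") are exchanged as SAM/BAM records carrying
base-modification calls in the standard MM/ML optional fields: m6dA
(exogenous adenine methylation, the accessibility channel) as ``A+a`` and
CpG m5dC (endogenous methylation) as ``C+m``.  Probabilities are byte-scaled
per the SAM base-modification convention: the ML byte ``b`` decodes to
``b / 256`` and encoding quantizes to the containing 1/256 bin.

Coordinates are 0-based, half-open everywhere; modification positions are
fiber-local offsets into the stored (forward) sequence.  MM payloads are
written in implicit-unmodified mode (no ``?`` flag): skipped bases of the
relevant type are treated as unmodified, which matches common
modification-caller output.
"""

from __future__ import annotations

import array
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .errors import FormatError

# custom SAM tags used for the hairpin adapter barcodes flanking a molecule
TAG_BARCODE_LEFT = "lb"
TAG_BARCODE_RIGHT = "rb"


@dataclass
class Fiber:
    """One aligned single molecule with per-base modification probabilities.

    ``a_positions`` / ``m6da_prob`` hold the adenine (accessibility channel)
    offsets and probabilities; ``cpg_positions`` / ``m5dc_prob`` hold CpG
    dyads, one entry per dyad at the top-strand C offset.
    """

    molecule_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    sequence: str | None = None
    a_positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    m6da_prob: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.float64))
    cpg_positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    m5dc_prob: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.float64))
    barcode_left: str = ""
    barcode_right: str = ""

    def __post_init__(self) -> None:
        self.a_positions = np.asarray(self.a_positions, dtype=np.int64)
        self.m6da_prob = np.asarray(self.m6da_prob, dtype=np.float64)
        self.cpg_positions = np.asarray(self.cpg_positions, dtype=np.int64)
        self.m5dc_prob = np.asarray(self.m5dc_prob, dtype=np.float64)

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    def validate(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError(f"{self.molecule_id}: empty span")
        if self.sequence is not None and len(self.sequence) != self.length_nt:
            raise ValueError(f"{self.molecule_id}: sequence length != span")
        for name, pos, prob in (
            ("a", self.a_positions, self.m6da_prob),
            ("cpg", self.cpg_positions, self.m5dc_prob),
        ):
            if len(pos) != len(prob):
                raise ValueError(f"{self.molecule_id}: {name} positions/probs length mismatch")
            if len(pos):
                if pos[0] < 0 or pos[-1] >= self.length_nt:
                    raise ValueError(f"{self.molecule_id}: {name} offsets out of [0, length)")
                if np.any(np.diff(pos) <= 0):
                    raise ValueError(f"{self.molecule_id}: {name} offsets not strictly increasing")
                if prob.min() < 0 or prob.max() > 1:
                    raise ValueError(f"{self.molecule_id}: {name} probabilities outside [0, 1]")


@dataclass
class AlignmentStats:
    n_matches: int
    n_mismatches: int
    n_del: int
    n_ins: int

    @property
    def total(self) -> int:
        return self.n_matches + self.n_mismatches + self.n_del + self.n_ins


@dataclass
class BarcodeSet:
    """Fixed-length DNA barcodes with one sample label per barcode."""

    barcodes: list[str]
    sample_labels: list[str]

    def __post_init__(self) -> None:
        if len(self.barcodes) != len(self.sample_labels):
            raise ValueError("one sample label per barcode required")
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) > 1:
            raise ValueError("barcodes must share a single length")

    def min_pairwise_distance(self) -> int:
        codes = self.barcodes
        if len(codes) < 2:
            return len(codes[0]) if codes else 0
        return min(
            hamming(codes[i], codes[j])
            for i in range(len(codes))
            for j in range(i + 1, len(codes))
        )

    def validate(self, min_dist: int = 4) -> None:
        if len(self.barcodes) >= 2 and self.min_pairwise_distance() < min_dist:
            raise ValueError(f"barcode set violates minimum Hamming distance {min_dist}")


@dataclass
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval {self.chrom}:{self.start}-{self.end} is empty")
        if self.start < 0:
            raise ValueError(f"negative coordinate in {self.chrom}:{self.start}-{self.end}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


# ---------------------------------------------------------------------------
# MM/ML codec
# ---------------------------------------------------------------------------

_ML_SCALE = 256.0


def parse_mod_probs(record: pysam.AlignedSegment) -> Fiber:
    """Decode a SAM/BAM record's MM/ML payload into a :class:`Fiber`.

    m6dA calls are read from the ``(A, +, a)`` channel and CpG m5dC from
    ``(C, +, m)``; offsets are positions in the stored sequence.
    """
    try:
        mods = record.modified_bases
    except (ValueError, KeyError, TypeError) as exc:  # pragma: no cover - pysam detail
        raise FormatError(f"{record.query_name}: malformed MM/ML tags ({exc})") from exc
    if mods is None:
        raise FormatError(f"{record.query_name}: malformed MM/ML tags")

    def _channel(base: str, code: str) -> tuple[np.ndarray, np.ndarray]:
        calls = mods.get((base, 0, code), [])
        if not calls:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.float64)
        pos = np.array([p for p, _ in calls], dtype=np.int64)
        prob = np.array([q for _, q in calls], dtype=np.float64) / _ML_SCALE
        order = np.argsort(pos)
        return pos[order], prob[order]

    a_pos, a_prob = _channel("A", "a")
    c_pos, c_prob = _channel("C", "m")
    start = record.reference_start if record.reference_start >= 0 else 0
    length = record.query_length or len(record.query_sequence or "")
    fiber = Fiber(
        molecule_id=record.query_name,
        chrom=record.reference_name or "*",
        start=start,
        end=start + length,
        strand="-" if record.is_reverse else "+",
        sequence=record.query_sequence,
        a_positions=a_pos,
        m6da_prob=a_prob,
        cpg_positions=c_pos,
        m5dc_prob=c_prob,
        barcode_left=record.get_tag(TAG_BARCODE_LEFT) if record.has_tag(TAG_BARCODE_LEFT) else "",
        barcode_right=record.get_tag(TAG_BARCODE_RIGHT) if record.has_tag(TAG_BARCODE_RIGHT) else "",
    )
    fiber.validate()
    return fiber


def _mm_deltas(base_offsets: np.ndarray, mod_offsets: np.ndarray) -> np.ndarray:
    """Delta-encode modified offsets as counts of skipped same-base positions."""
    idx = np.searchsorted(base_offsets, mod_offsets)
    if not np.array_equal(base_offsets[idx], mod_offsets):
        raise ValueError("modified offset does not fall on the declared base")
    return np.diff(np.concatenate(([-1], idx))) - 1


def encode_mod_probs(
    fiber: Fiber, header: pysam.AlignmentHeader | None = None
) -> pysam.AlignedSegment:
    """Build an aligned record whose MM/ML decode reproduces the fiber.

    The record is written against the fiber's stored (forward) sequence with
    a single-block match CIGAR; probabilities quantize to 1/256.
    """
    fiber.validate()
    seq = fiber.sequence if fiber.sequence is not None else _synthesize_sequence(fiber)
    rec = pysam.AlignedSegment(header)
    rec.query_name = fiber.molecule_id
    rec.query_sequence = seq
    rec.flag = 0
    if header is not None and fiber.chrom in header.references:
        rec.reference_id = header.references.index(fiber.chrom)
        rec.reference_start = fiber.start
        rec.cigartuples = [(0, len(seq))]
        rec.mapping_quality = 60
    else:
        rec.reference_id = -1
        rec.flag = 4

    seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    mm_parts: list[str] = []
    ml_bytes: list[int] = []
    for base, code, offsets, probs in (
        ("A", "a", fiber.a_positions, fiber.m6da_prob),
        ("C", "m", fiber.cpg_positions, fiber.m5dc_prob),
    ):
        if len(offsets) == 0:
            continue
        if offsets[-1] >= len(seq):
            raise ValueError(f"{fiber.molecule_id}: modification offset beyond record length")
        base_offsets = np.flatnonzero(seq_arr == ord(base))
        deltas = _mm_deltas(base_offsets, offsets)
        mm_parts.append(f"{base}+{code}," + ",".join(str(d) for d in deltas) + ";")
        ml_bytes.extend(int(min(b, 255)) for b in np.floor(probs * _ML_SCALE).astype(np.int64))
    if mm_parts:
        rec.set_tag("MM", "".join(mm_parts), value_type="Z")
        rec.set_tag("ML", array.array("B", ml_bytes))
    if fiber.barcode_left:
        rec.set_tag(TAG_BARCODE_LEFT, fiber.barcode_left, value_type="Z")
    if fiber.barcode_right:
        rec.set_tag(TAG_BARCODE_RIGHT, fiber.barcode_right, value_type="Z")
    return rec


def _synthesize_sequence(fiber: Fiber) -> str:
    """Minimal sequence consistent with a fiber's annotated A and CpG offsets."""
    seq = np.full(fiber.length_nt, ord("T"), dtype=np.uint8)
    for p in fiber.cpg_positions:
        if p + 1 >= fiber.length_nt:
            raise ValueError(f"{fiber.molecule_id}: CpG at fiber edge has no room for G")
        seq[p] = ord("C")
        seq[p + 1] = ord("G")
    seq[fiber.a_positions] = ord("A")
    return seq.tobytes().decode()


# ---------------------------------------------------------------------------
# Read quality
# ---------------------------------------------------------------------------


def empiric_q(stats: AlignmentStats, cap: float = 60.0, phred: bool = True) -> float:
    """Empiric read quality from alignment event counts.

    The error fraction is ``1 - n_matches / total`` over matches, mismatches,
    deletions and insertions.  With ``phred=True`` (default) the value is
    Phred-scaled (``-10 log10``); ``phred=False`` gives the bare ``-log10``
    form.  Reads with no variation return ``cap``, the maximal theoretical
    quality score.
    """
    if stats.total <= 0:
        raise ValueError("empiric_q requires at least one alignment event")
    if min(stats.n_matches, stats.n_mismatches, stats.n_del, stats.n_ins) < 0:
        raise ValueError("negative alignment event count")
    if stats.n_mismatches == 0 and stats.n_del == 0 and stats.n_ins == 0:
        return float(cap)
    q = -math.log10(1.0 - stats.n_matches / stats.total)
    return 10.0 * q if phred else q


# ---------------------------------------------------------------------------
# Barcodes
# ---------------------------------------------------------------------------


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def _nearest_barcode(code: str, barcode_set: BarcodeSet, max_dist: int) -> int | None:
    dists = [hamming(code, b) for b in barcode_set.barcodes]
    best = min(dists)
    if best > max_dist or dists.count(best) > 1:
        return None
    return dists.index(best)


def demultiplex(
    fiber: Fiber, barcode_set: BarcodeSet, max_dist: int = 1
) -> tuple[str | None, bool]:
    """Assign a fiber to a sample by nearest-barcode decoding of both ends.

    Each end is decoded to the unique nearest barcode within ``max_dist``
    substitutions; ties or excessive distance leave the end unassigned.  The
    fiber is assigned only when both ends decode to the same barcode
    (``concordant=True``); anything else returns ``(None, False)``.
    """
    if not fiber.barcode_left or not fiber.barcode_right:
        return None, False
    left = _nearest_barcode(fiber.barcode_left, barcode_set, max_dist)
    right = _nearest_barcode(fiber.barcode_right, barcode_set, max_dist)
    if left is not None and left == right:
        return barcode_set.sample_labels[left], True
    return None, False


# ---------------------------------------------------------------------------
# BED / TSV / alignment files
# ---------------------------------------------------------------------------


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ into 0-based half-open intervals, sorted per chromosome."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    intervals: list[GenomicInterval] = []
    for row in df.itertuples(index=False):
        fields = list(row)
        try:
            start, end = int(fields[1]), int(fields[2])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"unparsable BED coordinates in {path}: {fields[:3]}") from exc
        name = str(fields[3]) if len(fields) > 3 and pd.notna(fields[3]) else "."
        strand = str(fields[5]) if len(fields) > 5 and pd.notna(fields[5]) else "."
        try:
            intervals.append(GenomicInterval(str(fields[0]), start, end, name, strand))
        except ValueError as exc:
            raise FormatError(f"invalid BED interval in {path}: {exc}") from exc
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_bed(intervals: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def write_tsv(frame: pd.DataFrame, path) -> None:
    """Header-bearing TSV with deterministic column order."""
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def alignment_header(chrom_lengths: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": int(length)} for name, length in chrom_lengths.items()],
        }
    )


def write_fibers(path, fibers, chrom_lengths: dict[str, int]) -> None:
    """Write fibers as SAM (``.sam``) or BAM (anything else) with MM/ML tags."""
    header = alignment_header(chrom_lengths)
    mode = "w" if str(path).endswith(".sam") else "wb"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for fiber in fibers:
            out.write(encode_mod_probs(fiber, header))


def read_fibers(path) -> list[Fiber]:
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        return [parse_mod_probs(rec) for rec in fh]
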