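"""Ground-truth chromatin fiber and tagmentation simulator.

Generates synthetic single molecules with planted nucleosome arrays,
CTCF-style motif footprints and CpG methylation classes, then fragments
them with a transposase insertion model.  The simulator emits calibrated
per-base modification probabilities directly (Beta noise around
state-dependent means), standing upstream of the analysis exactly where a
kinetics-based modification caller would sit.

Geometry conventions:

* nucleosomes protect ``nucleosome_len`` (147) nt; linkers between them are
  accessible unless occluded (``linker_accessible_prob``);
* ``in_situ`` transposition inserts only at accessible positions (the
  nucleosomal barrier effect), ``ex_situ`` inserts uniformly on naked DNA;
* each insertion produces a 9-bp target-site duplication, so consecutive
  fragments share a duplicated 9-nt junction after gap repair.

Truth annotations (planted footprints, fiber-type labels, insertion sites)
ride along with every fiber and fragment and serve as the oracle for the
downstream analysis modules.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CapacityError
from .io import BarcodeSet, Fiber, GenomicInterval, hamming, write_bed, write_fibers, write_tsv

DUPLICATION_LEN = 9  # target-site duplication left by the transposase
NUCLEOSOME_LEN = 147
MIN_LINKER = 5

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class FiberTypeSpec:
    """Generative description of one fiber type.

    ``kind`` selects the linker model: ``regular`` tiles nucleosomes with
    near-constant linkers (repeat length ``nrl_mean``), ``irregular`` draws
    exponential linkers (no repeat length), ``hyperaccessible`` leaves at
    least 80% of the fiber nucleosome-free, and ``ctcf_bound`` plants a
    short central motif footprint with phased flanking nucleosomes.
    """

    label: str
    kind: str = "regular"
    nrl_mean: float = 185.0
    nrl_sd: float = 5.0
    nucleosome_len: int = NUCLEOSOME_LEN
    linker_accessible_prob: float = 0.85
    ctcf_footprint_len: int = 45
    mixture_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in {"regular", "irregular", "hyperaccessible", "ctcf_bound"}:
            raise ValueError(f"unknown fiber kind {self.kind!r}")
        if self.kind == "regular" and self.nrl_mean <= self.nucleosome_len:
            raise ValueError("regular fibers need nrl_mean > nucleosome_len")


@dataclass
class NoiseModel:
    """Beta-noise model for emitted per-base modification probabilities.

    ``prob_dispersion`` is the Beta concentration; ``inf`` emits the state
    mean exactly (the noiseless limit).
    """

    p_meth_accessible: float = 0.9
    p_meth_footprint: float = 0.05
    prob_dispersion: float = 10.0
    cpg_meth_high: float = 0.85
    cpg_meth_low: float = 0.15

    def __post_init__(self) -> None:
        if not self.p_meth_accessible > self.p_meth_footprint:
            raise ValueError("p_meth_accessible must exceed p_meth_footprint")


@dataclass
class FiberTruth:
    """Planted ground truth for one parent fiber."""

    molecule_id: str
    type_label: str
    kind: str
    nrl_mean: float
    nucleosomes: list[tuple[int, int]]
    protected_intervals: list[tuple[int, int]]  # maximal protected runs (the planted footprints)
    ctcf_interval: tuple[int, int] | None
    cpg_island: bool
    cpg_methylated: bool
    insertion_sites: list[int] = field(default_factory=list)  # fiber-local, filled by tagmentation
    sample_label: str = ""


@dataclass
class FragmentTruth:
    """Ground truth for one tagmentation fragment, in fragment-local coordinates."""

    fragment_id: str
    source_molecule_id: str
    type_label: str
    span: tuple[int, int]  # fiber-local [start, end) of the fragment
    protected_intervals: list[tuple[int, int]]
    left_junction: bool  # fragment begins at a duplicated insertion junction
    right_junction: bool


@dataclass
class SimConfig:
    """Study conditions for a full synthetic dataset."""

    seed: int
    n_fibers: int = 100
    fiber_length: int = 20_000
    genome_fasta: str | None = None
    gc: float = 0.41
    fiber_type_specs: list[FiberTypeSpec] = field(default_factory=lambda: default_fiber_mixture())
    noise: NoiseModel = field(default_factory=NoiseModel)
    mode: str = "in_situ"
    tn5_density: float = 0.5  # expected insertions per eligible kb
    min_fragment_len: int = 500
    n_barcodes: int = 8
    barcode_length: int = 8
    barcode_min_dist: int = 4
    p_cpg_island: float = 0.25
    p_island_methylated: float = 0.2
    p_nonisland_methylated: float = 0.8

    def __post_init__(self) -> None:
        if self.mode not in {"in_situ", "ex_situ"}:
            raise ValueError("mode must be in_situ or ex_situ")
        if self.tn5_density < 0 or self.fiber_length <= 0:
            raise ValueError("rates and lengths must be positive")


def default_fiber_mixture() -> list[FiberTypeSpec]:
    """Default mixture: three regular repeat lengths plus irregular fibers,
    spanning the repeat-length range seen on real chromatin (roughly 170-210 nt)."""
    return [
        FiberTypeSpec("NRL172", "regular", nrl_mean=172.0, mixture_weight=0.3),
        FiberTypeSpec("NRL185", "regular", nrl_mean=185.0, mixture_weight=0.3),
        FiberTypeSpec("NRL208", "regular", nrl_mean=208.0, mixture_weight=0.2),
        FiberTypeSpec("IR", "irregular", nrl_mean=250.0, mixture_weight=0.2),
    ]


# ---------------------------------------------------------------------------
# Barcode design
# ---------------------------------------------------------------------------


def _max_homopolymer(code: str) -> int:
    best = run = 1
    for a, b in zip(code, code[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def design_barcodes(
    n: int, length: int = 8, min_dist: int = 4, seed: int = 0, max_attempts: int | None = None
) -> BarcodeSet:
    """Greedy random design of ``n`` barcodes with pairwise Hamming distance
    at least ``min_dist`` and homopolymer runs of at most 3 nt."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    budget = max_attempts if max_attempts is not None else 2000 * n
    picked: list[str] = []
    attempts = 0
    while len(picked) < n:
        attempts += 1
        if attempts > budget:
            raise CapacityError(
                f"could not place {n} barcodes of length {length} at distance {min_dist}"
            )
        cand = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
        if _max_homopolymer(cand) > 3:
            continue
        if all(hamming(cand, b) >= min_dist for b in picked):
            picked.append(cand)
    return BarcodeSet(picked, [f"S{i + 1}" for i in range(n)])


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------


def random_sequence(
    length: int,
    rng: np.random.Generator,
    gc: float = 0.41,
    cpg_per_kb: float | None = None,
) -> str:
    """Random sequence with given GC content and, optionally, a target CpG
    dinucleotide density (per kb), emulating CpG depletion vs islands."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    seq = _BASES[rng.choice(4, size=length, p=p)]
    if cpg_per_kb is not None:
        is_c = seq[:-1] == ord("C")
        is_g = seq[1:] == ord("G")
        cg_starts = np.flatnonzero(is_c & is_g)
        target = cpg_per_kb * length / 1000.0
        if len(cg_starts) > target:
            # thin CpGs down to the target by mutating the G
            drop = rng.choice(
                cg_starts, size=int(round(len(cg_starts) - target)), replace=False
            )
            seq[drop + 1] = ord("T")
        else:
            # plant additional CpGs at random non-overlapping positions
            need = int(round(target - len(cg_starts)))
            if need > 0 and length > 2:
                cand = rng.choice(length - 1, size=min(4 * need, length - 1), replace=False)
                placed = 0
                for s in cand:
                    if placed >= need:
                        break
                    if seq[s] == ord("C") and seq[s + 1] == ord("G"):
                        continue
                    seq[s] = ord("C")
                    seq[s + 1] = ord("G")
                    placed += 1
    return seq.tobytes().decode()


def _find_cpg(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))


# ---------------------------------------------------------------------------
# Single-fiber simulation
# ---------------------------------------------------------------------------


def _draw_linker(spec: FiberTypeSpec, rng: np.random.Generator) -> int:
    mean_linker = spec.nrl_mean - spec.nucleosome_len
    if spec.kind in {"regular", "ctcf_bound"}:
        if spec.nrl_sd == 0:
            return int(round(mean_linker))
        return int(round(max(MIN_LINKER, rng.normal(mean_linker, spec.nrl_sd))))
    if spec.kind == "irregular":
        return int(round(max(MIN_LINKER, rng.exponential(mean_linker))))
    # hyperaccessible: long exponential linkers keeping occupancy low
    scale = spec.nucleosome_len * (1 / 0.15 - 1)
    return int(round(max(MIN_LINKER, rng.exponential(scale))))


def _plant_nucleosomes(
    spec: FiberTypeSpec, length: int, rng: np.random.Generator
) -> tuple[list[tuple[int, int]], tuple[int, int] | None]:
    """Place nucleosome intervals (and a central motif footprint for
    ``ctcf_bound`` fibers).  A terminal nucleosome clipped by the fiber end
    is kept only when at least half of it fits."""
    nuc = spec.nucleosome_len
    nucleosomes: list[tuple[int, int]] = []
    ctcf: tuple[int, int] | None = None

    def _tile(start: int, stop: int, forward: bool = True) -> list[tuple[int, int]]:
        out: list[tuple[int, int]] = []
        pos = start
        if forward:
            pos = start + _draw_linker(spec, rng)
            while pos < stop:
                end = min(pos + nuc, stop)
                if end - pos >= (nuc + 1) // 2:
                    out.append((pos, end))
                pos = pos + nuc + _draw_linker(spec, rng)
        else:
            pos = start - _draw_linker(spec, rng)
            while pos > stop:
                s = max(pos - nuc, stop)
                if pos - s >= (nuc + 1) // 2:
                    out.append((s, pos))
                pos = pos - nuc - _draw_linker(spec, rng)
            out.reverse()
        return out

    if spec.kind == "ctcf_bound":
        c = length // 2
        half = spec.ctcf_footprint_len // 2
        ctcf = (c - half, c - half + spec.ctcf_footprint_len)
        nucleosomes = _tile(ctcf[0], 0, forward=False) + _tile(ctcf[1], length, forward=True)
    elif spec.kind == "hyperaccessible":
        budget = 0.2 * length
        covered = 0
        for s, e in _tile(0, length):
            if covered + (e - s) > budget:
                break
            nucleosomes.append((s, e))
            covered += e - s
    else:
        nucleosomes = _tile(0, length)
    return nucleosomes, ctcf


def _merge_protected(
    nucleosomes: list[tuple[int, int]],
    ctcf: tuple[int, int] | None,
    occluded_linkers: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    pieces = sorted(nucleosomes + occluded_linkers + ([ctcf] if ctcf else []))
    merged: list[tuple[int, int]] = []
    for s, e in pieces:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _beta_sample(
    mean: float, dispersion: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    if not np.isfinite(dispersion):
        return np.full(size, mean, dtype=np.float64)
    mean = min(max(mean, 1e-6), 1 - 1e-6)
    return rng.beta(mean * dispersion, (1 - mean) * dispersion, size=size)


def _membership(positions: np.ndarray, intervals: list[tuple[int, int]]) -> np.ndarray:
    """Boolean mask of positions falling inside any (sorted, disjoint) interval."""
    if not intervals or len(positions) == 0:
        return np.zeros(len(positions), dtype=bool)
    bounds = np.array(intervals).ravel()
    return (np.searchsorted(bounds, positions, side="right") % 2).astype(bool)


def simulate_fiber(
    spec: FiberTypeSpec,
    length: int,
    noise: NoiseModel,
    rng: np.random.Generator,
    *,
    molecule_id: str = "fiber0",
    chrom: str = "chrS",
    start: int = 0,
    sequence: str | None = None,
    gc: float = 0.41,
    cpg_island: bool = False,
    cpg_methylated: bool = False,
) -> tuple[Fiber, FiberTruth]:
    """Simulate one chromatin fiber with planted footprints and Beta-noise
    modification probabilities; returns the fiber and its ground truth."""
    if length < spec.nucleosome_len:
        raise ValueError("fiber shorter than one nucleosome")
    if sequence is None:
        sequence = random_sequence(
            length, rng, gc=gc, cpg_per_kb=33.0 if cpg_island else 5.0
        )
    nucleosomes, ctcf = _plant_nucleosomes(spec, length, rng)

    # occlude a fraction of interior linkers so multi-nucleosome footprints occur
    occluded: list[tuple[int, int]] = []
    for (s0, e0), (s1, e1) in zip(nucleosomes, nucleosomes[1:]):
        if rng.random() > spec.linker_accessible_prob:
            occluded.append((e0, s1))
    protected = _merge_protected(nucleosomes, ctcf, occluded)

    seq_arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    a_pos = np.flatnonzero(seq_arr == ord("A"))
    inside = _membership(a_pos, protected)
    a_prob = np.empty(len(a_pos), dtype=np.float64)
    a_prob[inside] = _beta_sample(noise.p_meth_footprint, noise.prob_dispersion, int(inside.sum()), rng)
    a_prob[~inside] = _beta_sample(
        noise.p_meth_accessible, noise.prob_dispersion, int((~inside).sum()), rng
    )

    cpg_pos = _find_cpg(sequence)
    meth_mean = noise.cpg_meth_high if cpg_methylated else noise.cpg_meth_low
    cpg_prob = _beta_sample(meth_mean, noise.prob_dispersion, len(cpg_pos), rng)
    if spec.kind == "ctcf_bound" and ctcf is not None and len(cpg_pos):
        # bound motifs sit in locally unmethylated DNA
        near = (cpg_pos >= ctcf[0] - 50) & (cpg_pos < ctcf[1] + 50)
        cpg_prob[near] = _beta_sample(
            noise.cpg_meth_low, noise.prob_dispersion, int(near.sum()), rng
        )

    fiber = Fiber(
        molecule_id=molecule_id,
        chrom=chrom,
        start=start,
        end=start + length,
        sequence=sequence,
        a_positions=a_pos,
        m6da_prob=a_prob,
        cpg_positions=cpg_pos,
        m5dc_prob=cpg_prob,
    )
    truth = FiberTruth(
        molecule_id=molecule_id,
        type_label=spec.label,
        kind=spec.kind,
        nrl_mean=spec.nrl_mean,
        nucleosomes=nucleosomes,
        protected_intervals=protected,
        ctcf_interval=ctcf,
        cpg_island=cpg_island,
        cpg_methylated=cpg_methylated,
    )
    return fiber, truth


# ---------------------------------------------------------------------------
# Tagmentation
# ---------------------------------------------------------------------------


def _accessible_positions(length: int, protected: list[tuple[int, int]]) -> np.ndarray:
    mask = np.ones(length, dtype=bool)
    for s, e in protected:
        mask[s:e] = False
    return np.flatnonzero(mask)


def simulate_tagmentation(
    fibers_with_truth: list[tuple[Fiber, FiberTruth]],
    mode: str,
    tn5_density: float,
    barcodes: BarcodeSet,
    rng: np.random.Generator,
    *,
    min_fragment_len: int = 500,
    barcode_discordance: float = 0.001,
) -> tuple[list[Fiber], list[FragmentTruth]]:
    """Fragment fibers by transposase insertion and return barcoded fragments.

    ``in_situ`` draws insertion sites only from accessible (linker)
    positions; ``ex_situ`` draws uniformly.  The expected number of
    insertions is ``tn5_density`` per eligible kb.  Consecutive fragments
    share a duplicated 9-nt junction; fragments shorter than
    ``min_fragment_len`` are dropped.  Only internal fragments (both ends
    made by the transposase) are emitted.
    """
    if mode not in {"in_situ", "ex_situ"}:
        raise ValueError("mode must be in_situ or ex_situ")
    fragments: list[Fiber] = []
    truths: list[FragmentTruth] = []
    n_codes = len(barcodes.barcodes)
    for fiber, truth in fibers_with_truth:
        length = fiber.length_nt
        if mode == "in_situ":
            eligible = _accessible_positions(length, truth.protected_intervals)
            eligible = eligible[eligible <= length - DUPLICATION_LEN]
        else:
            eligible = np.arange(0, length - DUPLICATION_LEN + 1)
        if len(eligible) == 0:
            warnings.warn(f"{fiber.molecule_id}: no eligible insertion positions; skipped")
            continue
        n_ins = rng.poisson(tn5_density * len(eligible) / 1000.0)
        n_ins = min(n_ins, len(eligible))
        sites = np.sort(rng.choice(eligible, size=n_ins, replace=False))
        truth.insertion_sites = [int(s) for s in sites]
        code_idx = int(rng.integers(0, n_codes))
        truth.sample_label = barcodes.sample_labels[code_idx]
        for k, (s, e_site) in enumerate(zip(sites[:-1], sites[1:])):
            frag_start, frag_end = int(s), int(e_site) + DUPLICATION_LEN
            if frag_end - frag_start < min_fragment_len:
                continue
            frag_id = f"{fiber.molecule_id}/f{k}"
            left_bc = barcodes.barcodes[code_idx]
            right_bc = left_bc
            if rng.random() < barcode_discordance and n_codes > 1:
                right_bc = barcodes.barcodes[(code_idx + 1) % n_codes]
            a_sel = (fiber.a_positions >= frag_start) & (fiber.a_positions < frag_end)
            c_sel = (fiber.cpg_positions >= frag_start) & (fiber.cpg_positions < frag_end - 1)
            fragments.append(
                Fiber(
                    molecule_id=frag_id,
                    chrom=fiber.chrom,
                    start=fiber.start + frag_start,
                    end=fiber.start + frag_end,
                    sequence=fiber.sequence[frag_start:frag_end] if fiber.sequence else None,
                    a_positions=fiber.a_positions[a_sel] - frag_start,
                    m6da_prob=fiber.m6da_prob[a_sel],
                    cpg_positions=fiber.cpg_positions[c_sel] - frag_start,
                    m5dc_prob=fiber.m5dc_prob[c_sel],
                    barcode_left=left_bc,
                    barcode_right=right_bc,
                )
            )
            local_protected = [
                (max(ps, frag_start) - frag_start, min(pe, frag_end) - frag_start)
                for ps, pe in truth.protected_intervals
                if pe > frag_start and ps < frag_end
            ]
            truths.append(
                FragmentTruth(
                    fragment_id=frag_id,
                    source_molecule_id=fiber.molecule_id,
                    type_label=truth.type_label,
                    span=(frag_start, frag_end),
                    protected_intervals=local_protected,
                    left_junction=True,
                    right_junction=True,
                )
            )
    return fragments, truths


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------


@dataclass
class SimDataset:
    """In-memory handle on a simulated dataset plus its on-disk paths."""

    fragments: list[Fiber]
    fragment_truth: list[FragmentTruth]
    fiber_truth: list[FiberTruth]
    parent_fibers: list[tuple[Fiber, FiberTruth]]
    barcodes: BarcodeSet
    paths: dict[str, Path]


def _genome_windows(config: SimConfig, rng: np.random.Generator):
    """Yield (chrom, start, sequence) windows for each parent fiber."""
    if config.genome_fasta is None:
        for i in range(config.n_fibers):
            yield "chrS", i * config.fiber_length, None
        return
    from pyfaidx import Fasta

    fasta = Fasta(config.genome_fasta)
    names = [n for n in fasta.keys() if len(fasta[n]) >= config.fiber_length]
    if not names:
        raise CapacityError("no reference sequence long enough for the requested fiber length")
    for _ in range(config.n_fibers):
        name = names[int(rng.integers(0, len(names)))]
        start = int(rng.integers(0, len(fasta[name]) - config.fiber_length + 1))
        seq = str(fasta[name][start : start + config.fiber_length]).upper()
        yield name, start, seq


def simulate_parent_fibers(
    config: SimConfig, rng: np.random.Generator
) -> list[tuple[Fiber, FiberTruth]]:
    specs = config.fiber_type_specs
    weights = np.array([s.mixture_weight for s in specs], dtype=float)
    weights = weights / weights.sum()
    out: list[tuple[Fiber, FiberTruth]] = []
    for i, (chrom, start, seq) in enumerate(_genome_windows(config, rng)):
        spec = specs[int(rng.choice(len(specs), p=weights))]
        island = bool(rng.random() < config.p_cpg_island)
        p_meth = config.p_island_methylated if island else config.p_nonisland_methylated
        methylated = bool(rng.random() < p_meth)
        out.append(
            simulate_fiber(
                spec,
                config.fiber_length,
                config.noise,
                rng,
                molecule_id=f"sim{i:06d}",
                chrom=chrom,
                start=start,
                sequence=seq,
                gc=config.gc,
                cpg_island=island,
                cpg_methylated=methylated,
            )
        )
    return out


def simulate_dataset(config: SimConfig, out_dir, alignment_format: str = "sam") -> SimDataset:
    """Compose barcode design, fiber simulation and tagmentation into a
    dataset on disk: an alignment file with MM/ML tags, a BED of truth
    footprints, and TSVs of truth labels.  Byte-identical for a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    barcodes = design_barcodes(
        config.n_barcodes, config.barcode_length, config.barcode_min_dist, seed=config.seed
    )
    parents = simulate_parent_fibers(config, rng)
    fragments, frag_truth = simulate_tagmentation(
        parents,
        config.mode,
        config.tn5_density,
        barcodes,
        rng,
        min_fragment_len=config.min_fragment_len,
    )

    if config.genome_fasta is None:
        chrom_lengths = {"chrS": max(1, config.n_fibers * config.fiber_length)}
    else:
        from pyfaidx import Fasta

        fasta = Fasta(config.genome_fasta)
        chrom_lengths = {name: len(fasta[name]) for name in fasta.keys()}

    ext = "sam" if alignment_format == "sam" else "bam"
    paths = {
        "alignment": out_dir / f"fragments.{ext}",
        "footprints": out_dir / "truth_footprints.bed",
        "fibers": out_dir / "truth_fibers.tsv",
        "fragments": out_dir / "truth_fragments.tsv",
        "barcodes": out_dir / "barcodes.tsv",
    }
    write_fibers(paths["alignment"], fragments, chrom_lengths)

    bed = [
        GenomicInterval(f.chrom, f.start + s, f.start + e, t.type_label)
        for f, t in parents
        for s, e in t.protected_intervals
    ]
    write_bed(bed, paths["footprints"])
    write_tsv(
        pd.DataFrame(
            {
                "molecule_id": [t.molecule_id for _, t in parents],
                "type_label": [t.type_label for _, t in parents],
                "kind": [t.kind for _, t in parents],
                "nrl_mean": [t.nrl_mean for _, t in parents],
                "cpg_island": [t.cpg_island for _, t in parents],
                "cpg_methylated": [t.cpg_methylated for _, t in parents],
                "n_insertions": [len(t.insertion_sites) for _, t in parents],
                "sample_label": [t.sample_label for _, t in parents],
            }
        ),
        paths["fibers"],
    )
    write_tsv(
        pd.DataFrame(
            {
                "fragment_id": [t.fragment_id for t in frag_truth],
                "source_molecule_id": [t.source_molecule_id for t in frag_truth],
                "type_label": [t.type_label for t in frag_truth],
                "start": [t.span[0] for t in frag_truth],
                "end": [t.span[1] for t in frag_truth],
            }
        ),
        paths["fragments"],
    )
    write_tsv(
        pd.DataFrame({"barcode": barcodes.barcodes, "sample_label": barcodes.sample_labels}),
        paths["barcodes"],
    )
    return SimDataset(fragments, frag_truth, [t for _, t in parents], parents, barcodes, paths)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
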