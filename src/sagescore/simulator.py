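"""Synthetic data generation: repeat-rich templates, paired-end reads with
substitution errors, and an exact exhaustive mapper.

Templates are built from a library of gene-sized sequence blocks derived
from one common ancestor, mutated so block pairs share a target identity
(mimicking multi-copy gene regions such as KIR).  Architectures arrange
blocks (with spacers) into haplotypes; reads are paired-end with a normal
insert-size distribution and uniform substitution errors.  The internal
mapper reports *every* placement of each end within a Hamming-distance
budget on both strands, using pigeonhole k-mer seeding so it is exact, then
pairs ends into concordant placements when orientations oppose and the
implied insert falls within mean +- 4 sd.

Also provides random convex matching instances for solver verification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from sagescore.csm_core import CoverageCostTable, MatchingInstance
from sagescore.instance_builder import Placement, ReadPlacementSet, ScoringParams

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = dict(zip(b"ACGT", b"TGCA"))
_RC_TABLE = bytes.maketrans(b"ACGTN", b"TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_ALPHABET, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with the given probability, always
    to a different base."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# block libraries and haplotype architectures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockLibrary:
    """Gene-sized blocks mutated from a shared ancestor.

    ``identity`` is the target pairwise Hamming identity between blocks,
    measured on the shared ancestor frame (i.e. position-by-position over
    the common prefix length).
    """

    blocks: tuple[tuple[str, str], ...]  # (block_id, sequence)
    identity: float
    rng_seed: int

    def sequence(self, block_id: str) -> str:
        for bid, seq in self.blocks:
            if bid == block_id:
                return seq
        raise KeyError(f"unknown block id {block_id!r}")


@dataclass(frozen=True)
class HaplotypeArchitecture:
    """Ordered block layout of one haplotype with inter-block spacer lengths.

    ``spacers[i]`` is the spacer following block ``i``; the list may be one
    shorter than ``block_ids`` (no trailing spacer).
    """

    block_ids: tuple[str, ...]
    spacers: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.spacers) not in (0, len(self.block_ids) - 1, len(self.block_ids)):
            raise ValueError("spacers must number len(blocks)-1, len(blocks) or 0")


def _per_copy_mutation_rate(identity: float) -> float:
    # two copies mutated at rate q agree per site with prob (1-q)^2 + q^2/3;
    # solve (4/3) q^2 - 2 q + (1 - identity) = 0 for the small root
    disc = 4.0 - (16.0 / 3.0) * (1.0 - identity)
    if disc < 0:
        raise ValueError(f"pairwise identity {identity} is unachievable")
    return (2.0 - math.sqrt(disc)) / (8.0 / 3.0)


def make_block_library(
    n_blocks: int,
    length_range: tuple[int, int] = (4000, 16000),
    identity: float = 0.90,
    seed: int = 0,
) -> BlockLibrary:
    """Create ``n_blocks`` blocks whose pairwise identity targets ``identity``.

    Each block is an independently mutated copy of a common random ancestor;
    the per-copy substitution rate is calibrated so pairs of blocks meet the
    target.  Deterministic for a fixed seed.
    """
    if not 0.5 < identity <= 1.0:
        raise ValueError("identity must be in (0.5, 1.0]")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid length range")
    rng = np.random.default_rng(seed)
    ancestor = _random_dna(rng, hi)
    rate = _per_copy_mutation_rate(identity)
    blocks = []
    for k in range(n_blocks):
        length = int(rng.integers(lo, hi + 1))
        blocks.append((f"block{k}", _mutate(rng, ancestor[:length], rate)))
    return BlockLibrary(tuple(blocks), identity, seed)


def pairwise_identity(a: str, b: str) -> float:
    """Hamming identity over the common prefix (the shared ancestor frame)."""
    n = min(len(a), len(b))
    u = np.frombuffer(a[:n].encode(), dtype=np.uint8)
    v = np.frombuffer(b[:n].encode(), dtype=np.uint8)
    return float(np.mean(u == v))


def render_haplotype(arch: HaplotypeArchitecture, lib: BlockLibrary) -> str:
    """Concatenate the architecture's blocks with deterministic spacers.

    Spacer sequences are a function of the library seed and the spacer
    *length* only, so equal-length spacers are identical everywhere: any
    block junction of an architecture is preserved verbatim in architectures
    that duplicate or reorder blocks around it.
    """
    parts: list[str] = []
    spacers = list(arch.spacers)
    for i, bid in enumerate(arch.block_ids):
        parts.append(lib.sequence(bid))
        if i < len(spacers):
            length = spacers[i]
            if length:
                rng = np.random.default_rng((lib.rng_seed, 7919, length))
                parts.append(_random_dna(rng, length))
    return "".join(parts)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    seq2: str  # as sequenced (reverse strand of the fragment's right end)
    true_position: int  # leftmost template base of the first mate
    true_template: str


@dataclass(frozen=True)
class SimulatedReadSet:
    pairs: tuple[ReadPair, ...]
    template_id: str
    read_length: int
    insert_mean: float
    insert_sd: float
    error_rate: float
    coverage: float
    rng_seed: int


def simulate_reads(
    template: str,
    template_id: str = "template",
    coverage: float = 30.0,
    read_length: int = 100,
    insert_mean: float = 400.0,
    insert_sd: float = 40.0,
    error_rate: float = 0.005,
    seed: int = 0,
) -> SimulatedReadSet:
    """Simulate paired-end reads from one template sequence.

    The number of pairs is Poisson with mean ``coverage * len(template) /
    (2 * read_length)``; fragment starts are uniform; the second end is the
    reverse complement of the fragment's right end; substitution errors are
    uniform per base.  Deterministic for a fixed seed.
    """
    G = len(template)
    max_insert = int(insert_mean + 4 * insert_sd)
    if G < max_insert:
        raise ValueError(
            f"template of length {G} is shorter than the maximum insert {max_insert}"
        )
    rng = np.random.default_rng(seed)
    n_pairs = int(rng.poisson(coverage * G / (2 * read_length)))
    pairs: list[ReadPair] = []
    # inserts clipped into the concordance window (mean +- 4 sd) shared with
    # the mapper, so error-free pairs are always recoverable as concordant
    lo = max(2 * read_length, int(math.ceil(insert_mean - 4 * insert_sd)))
    hi = min(G, int(insert_mean + 4 * insert_sd))
    for k in range(n_pairs):
        insert = int(round(rng.normal(insert_mean, insert_sd)))
        insert = max(lo, min(insert, hi))
        start = int(rng.integers(0, G - insert + 1))
        frag = template[start : start + insert]
        end1 = frag[:read_length]
        end2 = reverse_complement(frag[-read_length:])
        if error_rate > 0:
            end1 = _mutate(rng, end1, error_rate)
            end2 = _mutate(rng, end2, error_rate)
        pairs.append(ReadPair(f"read{k:07d}", end1, end2, start, template_id))
    return SimulatedReadSet(
        tuple(pairs),
        template_id,
        read_length,
        insert_mean,
        insert_sd,
        error_rate,
        coverage,
        seed,
    )


# ---------------------------------------------------------------------------
# exhaustive mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EndHit:
    position: int  # leftmost aligned template base of this end
    strand: str  # "+" or "-"
    mismatches: int


class _HammingIndex:
    """Exact all-placements Hamming search via pigeonhole k-mer seeding.

    A read with at most ``m`` mismatches must contain one of its ``m + 1``
    disjoint chunks exactly, so seeding on every chunk and verifying each
    candidate start yields every placement within the budget.
    """

    def __init__(self, template: str, read_length: int, max_mismatches: int):
        self.template = template
        self.arr = np.frombuffer(template.encode(), dtype=np.uint8)
        self.read_length = read_length
        self.max_mismatches = max_mismatches
        self.chunk = max(1, read_length // (max_mismatches + 1))
        self.n_chunks = max_mismatches + 1
        index: dict[bytes, list[int]] = {}
        enc = template.encode()
        for pos in range(len(template) - self.chunk + 1):
            index.setdefault(enc[pos : pos + self.chunk], []).append(pos)
        self.index = index

    def hits(self, seq: str) -> list[EndHit]:
        out: list[EndHit] = []
        L = self.read_length
        if len(seq) != L or len(self.template) < L:
            return out
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            enc = s.encode()
            sarr = np.frombuffer(enc, dtype=np.uint8)
            starts: set[int] = set()
            for c in range(self.n_chunks):
                off = c * self.chunk
                if off + self.chunk > L:
                    break
                for pos in self.index.get(enc[off : off + self.chunk], ()):
                    start = pos - off
                    if 0 <= start <= len(self.template) - L:
                        starts.add(start)
            for start in sorted(starts):
                mm = int(np.count_nonzero(self.arr[start : start + L] != sarr))
                if mm <= self.max_mismatches:
                    out.append(EndHit(start, strand, mm))
        return out


def exhaustive_map(
    reads: SimulatedReadSet, template: str, params: ScoringParams
) -> list[ReadPlacementSet]:
    """Map every read pair to every candidate placement on the template.

    Per end, all positions on both strands within the mismatch budget are
    found; end pairs in opposing orientation whose implied insert lies in
    ``insert_mean +- 4 insert_sd`` become concordant placements costed at
    ``(mm1 + mm2) * mismatch_cost``; end hits in no concordant combination
    become discordant placements at their own position with the discordant
    penalty added.
    """
    idx = _HammingIndex(template, reads.read_length, params.max_mismatches_per_end)
    lo = params.insert_mean - 4 * params.insert_sd
    hi = params.insert_mean + 4 * params.insert_sd
    L = reads.read_length
    out: list[ReadPlacementSet] = []
    for pair in reads.pairs:
        hits1 = idx.hits(pair.seq1)
        hits2 = idx.hits(pair.seq2)
        placements: list[Placement] = []
        used1: set[int] = set()
        used2: set[int] = set()
        for i, h1 in enumerate(hits1):
            for j, h2 in enumerate(hits2):
                if h1.strand == h2.strand:
                    continue
                left, right = (h1, h2) if h1.position <= h2.position else (h2, h1)
                if left.strand != "+" or right.strand != "-":
                    continue
                insert = right.position + L - left.position
                if not lo <= insert <= hi:
                    continue
                cost = (h1.mismatches + h2.mismatches) * params.mismatch_cost
                placements.append(Placement(h1.position, cost, concordant=True))
                used1.add(i)
                used2.add(j)
        for i, h in enumerate(hits1):
            if i not in used1:
                placements.append(
                    Placement(
                        h.position,
                        h.mismatches * params.mismatch_cost + params.discordant_penalty,
                        concordant=False,
                    )
                )
        for j, h in enumerate(hits2):
            if j not in used2:
                placements.append(
                    Placement(
                        h.position,
                        h.mismatches * params.mismatch_cost + params.discordant_penalty,
                        concordant=False,
                    )
                )
        placements.sort(key=lambda p: (p.position, p.cost, not p.concordant))
        out.append(ReadPlacementSet(pair.read_id, tuple(placements)))
    return out


# ---------------------------------------------------------------------------
# file output (FASTA / FASTQ / SAM / truth table)
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> list[tuple[str, str]]:
    """Minimal FASTA reader returning (name, sequence) in file order."""
    records: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: SimulatedReadSet, path1: str, path2: str) -> None:
    qual = "I" * reads.read_length
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for pair in reads.pairs:
            f1.write(f"@{pair.read_id}/1\n{pair.seq1}\n+\n{qual}\n")
            f2.write(f"@{pair.read_id}/2\n{pair.seq2}\n+\n{qual}\n")


def write_truth(reads: SimulatedReadSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttrue_template\ttrue_position\n")
        for pair in reads.pairs:
            fh.write(f"{pair.read_id}\t{pair.true_template}\t{pair.true_position}\n")


def write_sam(
    reads: SimulatedReadSet,
    placements: Sequence[ReadPlacementSet],
    template: str,
    template_id: str,
    params: ScoringParams,
    path: str,
) -> None:
    """Write all candidate alignments as SAM with per-end cost tags.

    Concordant placements become proper-pair record pairs; discordant
    per-end placements become single non-proper records; fully unplaced
    reads get one unmapped record so the read set can be reconstructed.
    The per-record cost tag carries the *per-end* mismatch cost; pairing
    flags let the reader re-apply the concordant/discordant combination
    rules.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": template_id, "LN": len(template)}],
    }
    idx = _HammingIndex(template, reads.read_length, params.max_mismatches_per_end)
    lo = params.insert_mean - 4 * params.insert_sd
    hi = params.insert_mean + 4 * params.insert_sd
    L = reads.read_length
    by_id = {pair.read_id: pair for pair in reads.pairs}

    def new_rec(
        sam: pysam.AlignmentFile,
        name: str,
        seq: str,
        pos: int,
        flag: int,
        cost: float,
        mpos: int = -1,
    ) -> pysam.AlignedSegment:
        rec = pysam.AlignedSegment(sam.header)
        rec.query_name = name
        rec.flag = flag
        if flag & 0x4:
            rec.reference_id = -1
            rec.reference_start = -1
        else:
            rec.reference_id = 0
            rec.reference_start = pos
            rec.cigarstring = f"{L}M"
            rec.mapping_quality = 0
        rec.next_reference_id = 0 if mpos >= 0 else -1
        rec.next_reference_start = mpos
        rec.query_sequence = seq if not flag & 0x10 else reverse_complement(seq)
        rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        if not flag & 0x4:
            rec.set_tag(params.cost_tag, int(round(cost)), value_type="i")
        return rec

    with pysam.AlignmentFile(path, "w", header=header) as sam:
        for ps in placements:
            pair = by_id[ps.read_id]
            hits1 = idx.hits(pair.seq1)
            hits2 = idx.hits(pair.seq2)
            wrote_any = False
            used1: set[int] = set()
            used2: set[int] = set()
            for i, h1 in enumerate(hits1):
                for j, h2 in enumerate(hits2):
                    if h1.strand == h2.strand:
                        continue
                    left, right = (h1, h2) if h1.position <= h2.position else (h2, h1)
                    if left.strand != "+" or right.strand != "-":
                        continue
                    if not lo <= right.position + L - left.position <= hi:
                        continue
                    flag1 = 0x1 | 0x2 | 0x40 | (0x10 if h1.strand == "-" else 0x20)
                    flag2 = 0x1 | 0x2 | 0x80 | (0x10 if h2.strand == "-" else 0x20)
                    sam.write(
                        new_rec(
                            sam,
                            ps.read_id,
                            pair.seq1,
                            h1.position,
                            flag1,
                            h1.mismatches * params.mismatch_cost,
                            mpos=h2.position,
                        )
                    )
                    sam.write(
                        new_rec(
                            sam,
                            ps.read_id,
                            pair.seq2,
                            h2.position,
                            flag2,
                            h2.mismatches * params.mismatch_cost,
                            mpos=h1.position,
                        )
                    )
                    used1.add(i)
                    used2.add(j)
                    wrote_any = True
            for ends, used, first in ((hits1, used1, True), (hits2, used2, False)):
                seq = pair.seq1 if first else pair.seq2
                mate_flag = 0x40 if first else 0x80
                for i, h in enumerate(ends):
                    if i in used:
                        continue
                    flag = 0x1 | mate_flag | (0x10 if h.strand == "-" else 0)
                    sam.write(
                        new_rec(
                            sam,
                            ps.read_id,
                            seq,
                            h.position,
                            flag,
                            h.mismatches * params.mismatch_cost,
                        )
                    )
                    wrote_any = True
            if not wrote_any:
                sam.write(
                    new_rec(sam, ps.read_id, pair.seq1, -1, 0x1 | 0x4 | 0x8 | 0x40, 0.0)
                )


# ---------------------------------------------------------------------------
# random convex instances (solver verification)
# ---------------------------------------------------------------------------

def random_convex_table(
    rng: np.random.Generator, element_id: str, max_len: int = 5
) -> CoverageCostTable:
    """Random convex coverage table with integer costs.

    Convexity is enforced by construction: successive differences are drawn
    non-decreasing.
    """
    length = int(rng.integers(1, max_len + 1))
    costs = [float(rng.integers(0, 21))]
    slope = float(rng.integers(-10, 11))
    for _ in range(length - 1):
        costs.append(costs[-1] + slope)
        slope += float(rng.integers(0, 6))
    return CoverageCostTable(element_id, tuple(costs))


def random_convex_instance(
    rng: np.random.Generator,
    max_x: int = 5,
    max_y: int = 4,
    max_pairs: int = 12,
    max_cost: int = 20,
) -> MatchingInstance:
    """Random small convex instance for oracle-vs-solver comparisons."""
    nx = int(rng.integers(1, max_x + 1))
    ny = int(rng.integers(1, max_y + 1))
    X = tuple(f"x{i}" for i in range(nx))
    Y = tuple(f"y{j}" for j in range(ny))
    all_pairs = [(x, y) for x in X for y in Y]
    n_pairs = int(rng.integers(0, min(max_pairs, len(all_pairs)) + 1))
    chosen = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    costs = {
        all_pairs[int(k)]: float(rng.integers(0, max_cost + 1)) for k in chosen
    }
    tables = {z: random_convex_table(rng, z) for z in X + Y}
    return MatchingInstance(X, Y, costs, tables)
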