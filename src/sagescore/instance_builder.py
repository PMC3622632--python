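"""Turn read-to-template alignments into a convex-cost matching instance.

The template is partitioned into fixed-length segments (the last one may be
shorter) with expected coverage ``lambda = segment_length * |R| / |G|``
(scaled by length for the last segment).  Each read becomes an X element
with coverage costs ``{0: unmatched_penalty, 1: 0, >=2: +inf}``; each
segment becomes a Y element with a convex deviation cost around its
expected coverage (quadratic by default).  The matching cost of a
(read, segment) pair is the cheapest candidate placement of that read whose
position falls inside the segment.

Coordinates are 0-based half-open internally; SAM's 1-based POS is converted
on read.  A placement belongs to the segment containing its *start*
position, even if the alignment extends past the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pysam

from sagescore.csm_core import CoverageCostTable, InstanceError, MatchingInstance

INF = math.inf

_COVERAGE_KINDS = ("linear", "polynomial")


@dataclass(frozen=True)
class ScoringParams:
    """Scoring parameters, mirroring the flat parameter-file keys.

    ``flat_segment_costs`` is a test hook that zeroes all segment coverage
    costs, collapsing the score to the per-read closed form
    ``sum_x min(unmatched_penalty, best placement cost of x)``.
    """

    segment_length: int = 1000
    unmatched_penalty: float = 100.0
    discordant_penalty: float = 90.0
    coverage_cost_kind: str = "polynomial"
    coverage_exponent: float = 2.0
    expected_coverage: tuple[float, ...] | None = None
    mismatch_cost: float = 30.0
    max_mismatches_per_end: int = 3
    cost_tag: str = "ZC"
    insert_mean: float = 400.0
    insert_sd: float = 40.0
    flat_segment_costs: bool = False

    def __post_init__(self) -> None:
        if self.segment_length < 1:
            raise ValueError("segment_length must be >= 1")
        if self.unmatched_penalty < 0 or self.discordant_penalty < 0:
            raise ValueError("penalties must be nonnegative")
        if self.coverage_cost_kind not in _COVERAGE_KINDS:
            raise ValueError(
                f"coverage_cost_kind must be one of {_COVERAGE_KINDS}, "
                f"got {self.coverage_cost_kind!r}"
            )
        if self.coverage_exponent < 1:
            raise ValueError("coverage_exponent must be >= 1 (convexity)")
        if self.mismatch_cost < 0:
            raise ValueError("mismatch_cost must be nonnegative")
        if self.max_mismatches_per_end < 0:
            raise ValueError("max_mismatches_per_end must be nonnegative")


_PARAM_TYPES = {
    "segment_length": int,
    "unmatched_penalty": float,
    "discordant_penalty": float,
    "coverage_cost_kind": str,
    "coverage_exponent": float,
    "mismatch_cost": float,
    "max_mismatches_per_end": int,
    "cost_tag": str,
    "insert_mean": float,
    "insert_sd": float,
    "flat_segment_costs": lambda v: v.lower() in ("1", "true", "yes"),
    "expected_coverage": lambda v: tuple(float(x) for x in v.split(",")),
}


def load_params(path: str) -> ScoringParams:
    """Parse a flat ``key = value`` parameter file; unknown keys are errors."""
    values: dict[str, object] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in _PARAM_TYPES:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            values[key] = _PARAM_TYPES[key](val)
    return ScoringParams(**values)  # type: ignore[arg-type]


@dataclass(frozen=True)
class Placement:
    """One candidate location of a read pair on the template."""

    position: int  # 0-based start of the leftmost aligned base of the first mate
    cost: float
    concordant: bool = True


@dataclass(frozen=True)
class ReadPlacementSet:
    """All candidate placements of one read (pair) on one template."""

    read_id: str
    placements: tuple[Placement, ...] = ()

    @property
    def best_cost(self) -> float:
        return min((p.cost for p in self.placements), default=INF)


@dataclass(frozen=True)
class Segmentation:
    """Partition of ``[0, template_length)`` into fixed-length segments."""

    template_length: int
    segment_length: int
    boundaries: tuple[tuple[int, int], ...]
    expected_coverage: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.boundaries)

    def segment_of(self, position: int) -> int:
        if not 0 <= position < self.template_length:
            raise InstanceError(
                f"position {position} outside template [0, {self.template_length})"
            )
        return position // self.segment_length

    def segment_id(self, index: int) -> str:
        return f"seg{index:06d}"


def segment_template(
    template_length: int, n_reads: int, params: ScoringParams
) -> Segmentation:
    """Partition the template and assign per-segment expected coverage.

    Full segments get ``lambda = segment_length * n_reads / template_length``;
    the final, possibly shorter segment's lambda is scaled by its length so
    that the lambdas sum to ``n_reads`` exactly.  An explicit
    ``params.expected_coverage`` list overrides the computed values.
    """
    if template_length < 1:
        raise ValueError("template_length must be >= 1")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    L = params.segment_length
    n_seg = -(-template_length // L)  # ceil
    boundaries = tuple(
        (k * L, min((k + 1) * L, template_length)) for k in range(n_seg)
    )
    density = n_reads / template_length
    lambdas = tuple((end - start) * density for start, end in boundaries)
    if params.expected_coverage is not None:
        if len(params.expected_coverage) != n_seg:
            raise ValueError(
                f"expected_coverage override has {len(params.expected_coverage)} "
                f"entries for {n_seg} segments"
            )
        lambdas = tuple(float(v) for v in params.expected_coverage)
    return Segmentation(template_length, L, boundaries, lambdas)


def pair_cost(
    end1_cost: float | None,
    end2_cost: float | None,
    concordant: bool,
    params: ScoringParams,
) -> float | None:
    """Combine per-end alignment costs into one placement cost.

    Concordant placements sum both ends.  A lone mapped end (no concordant
    mate) pays its own cost plus the discordant penalty.  With neither end
    mapped the read has no placement (returns None) and contributes only its
    unmatched penalty through the coverage costs.
    """
    for c in (end1_cost, end2_cost):
        if c is not None and c < 0:
            raise ValueError("alignment costs must be nonnegative")
    if concordant:
        if end1_cost is None or end2_cost is None:
            raise ValueError("concordant placement requires both end costs")
        return end1_cost + end2_cost
    if end1_cost is not None and end2_cost is not None:
        raise ValueError(
            "discordant placements are per-end; combine one mapped end at a time"
        )
    single = end1_cost if end1_cost is not None else end2_cost
    if single is None:
        return None
    return single + params.discordant_penalty


def load_placements(
    alignment_path: str, template_id: str, params: ScoringParams
) -> list[ReadPlacementSet]:
    """Read candidate placements from a SAM/BAM file.

    Proper-pair records are joined mate-to-mate (via POS/PNEXT) into
    concordant placements positioned at the first mate's leftmost aligned
    base, with cost the sum of the two ends' cost tags.  Mapped records
    outside a proper pair each yield a discordant placement at their own
    position.  Reads whose records are all unmapped are retained with no
    placements.  Records missing the cost tag raise an error naming the read.
    """
    groups: dict[str, list[pysam.AlignedSegment]] = {}
    with pysam.AlignmentFile(alignment_path, require_index=False) as fh:
        if template_id not in fh.references:
            raise InstanceError(
                f"template {template_id!r} absent from {alignment_path} header"
            )
        for rec in fh.fetch(until_eof=True):
            if rec.is_supplementary:
                continue
            groups.setdefault(rec.query_name, []).append(rec)

    def end_cost(rec: pysam.AlignedSegment) -> float:
        try:
            return float(rec.get_tag(params.cost_tag))
        except KeyError:
            raise InstanceError(
                f"record {rec.query_name!r} at POS {rec.reference_start + 1} lacks "
                f"cost tag {params.cost_tag!r}"
            ) from None

    out: list[ReadPlacementSet] = []
    for name in sorted(groups):
        placements: list[Placement] = []
        first_mates: dict[tuple[int, int], list[pysam.AlignedSegment]] = {}
        second_mates: dict[tuple[int, int], list[pysam.AlignedSegment]] = {}
        for rec in groups[name]:
            if rec.is_unmapped:
                continue
            if rec.reference_name != template_id:
                continue
            if rec.is_proper_pair:
                key = (rec.reference_start, rec.next_reference_start)
                target = second_mates if rec.is_read2 else first_mates
                target.setdefault(key, []).append(rec)
            else:
                placements.append(
                    Placement(
                        rec.reference_start,
                        pair_cost(end_cost(rec), None, False, params),
                        concordant=False,
                    )
                )
        for (pos, mate_pos), recs1 in first_mates.items():
            recs2 = second_mates.get((mate_pos, pos), [])
            for r1, r2 in zip(recs1, recs2):
                placements.append(
                    Placement(
                        r1.reference_start,
                        pair_cost(end_cost(r1), end_cost(r2), True, params),
                        concordant=True,
                    )
                )
        placements.sort(key=lambda p: (p.position, p.cost, not p.concordant))
        out.append(ReadPlacementSet(name, tuple(placements)))
    return out


def _segment_cost_fn(lam: float, params: ScoringParams):
    if params.flat_segment_costs:
        return lambda i: 0.0
    if params.coverage_cost_kind == "linear":
        return lambda i: abs(lam - i)
    p = params.coverage_exponent
    return lambda i: abs(lam - i) ** p


def build_instance(
    placements: Sequence[ReadPlacementSet],
    segmentation: Segmentation,
    params: ScoringParams,
) -> MatchingInstance:
    """Assemble the matching instance from placements and a segmentation.

    X is the full read set (including reads with no placements), Y the
    segments.  Multiple placements of one read inside one segment collapse
    to the minimum cost.  Segment tables are tabulated for coverages
    ``0 .. d_y`` since coverage cannot exceed the number of candidate reads.
    """
    read_ids = [ps.read_id for ps in placements]
    if len(set(read_ids)) != len(read_ids):
        raise InstanceError("duplicate read ids in placements")
    X = tuple(read_ids)
    Y = tuple(segmentation.segment_id(k) for k in range(len(segmentation)))

    costs: dict[tuple[str, str], float] = {}
    for ps in placements:
        for p in ps.placements:
            seg = segmentation.segment_id(segmentation.segment_of(p.position))
            key = (ps.read_id, seg)
            if key not in costs or p.cost < costs[key]:
                costs[key] = p.cost

    d_y = {y: 0 for y in Y}
    for (_x, y) in costs:
        d_y[y] += 1

    tables: dict[str, CoverageCostTable] = {}
    for x in X:
        tables[x] = CoverageCostTable(x, (params.unmatched_penalty, 0.0))
    for k, y in enumerate(Y):
        f = _segment_cost_fn(segmentation.expected_coverage[k], params)
        tables[y] = CoverageCostTable(y, tuple(f(i) for i in range(d_y[y] + 1)))

    return MatchingInstance(X, Y, costs, tables)
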