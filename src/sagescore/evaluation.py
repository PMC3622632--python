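"""Template scoring, ranking, score-matrix normalization and coverage profiles.

Two scores are computed per template, both on the same placement costs so
they share a scale (lower is better):

* the coverage-sensitive score: optimal matching cost of the convex
  instance built from the placements; and
* a naive baseline that sums each read's single best placement cost,
  ignoring coverage (unplaced reads contribute the unmatched penalty).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from sagescore.csm_core import Matching, matching_cost
from sagescore.flow_solver import solve_csm
from sagescore.instance_builder import (
    ReadPlacementSet,
    ScoringParams,
    Segmentation,
    build_instance,
    segment_template,
)

INF = math.inf


@dataclass(frozen=True)
class TemplateScore:
    template_id: str
    sage_score: float
    naive_score: float
    matching: Matching
    coverage_profile: tuple[int, ...]
    unmatched_count: int
    segmentation: Segmentation


def naive_score(placements: Sequence[ReadPlacementSet], params: ScoringParams) -> float:
    """Sum of best placement costs; unplaced reads pay the unmatched penalty."""
    total = 0.0
    for ps in placements:
        best = ps.best_cost
        total += params.unmatched_penalty if math.isinf(best) else best
    return total


def coverage_profile(matching: Matching, segmentation: Segmentation) -> tuple[int, ...]:
    """Matched-read counts per segment, in coordinate order."""
    counts = [0] * len(segmentation)
    index = {segmentation.segment_id(k): k for k in range(len(segmentation))}
    for _x, y in matching.pairs:
        counts[index[y]] += 1
    return tuple(counts)


def profile_variance(counts: Sequence[int], segmentation: Segmentation) -> float:
    """Mean squared deviation of a coverage profile from the expected values."""
    if not counts:
        return 0.0
    return sum(
        (c - lam) ** 2 for c, lam in zip(counts, segmentation.expected_coverage)
    ) / len(counts)


def best_placement_profile(
    placements: Sequence[ReadPlacementSet], segmentation: Segmentation
) -> tuple[int, ...]:
    """Coverage profile implied by giving every read its single cheapest
    placement (position tie-break), i.e. the naive baseline's matching."""
    counts = [0] * len(segmentation)
    for ps in placements:
        if not ps.placements:
            continue
        best = min(ps.placements, key=lambda p: (p.cost, p.position))
        counts[segmentation.segment_of(best.position)] += 1
    return tuple(counts)


def score_template(
    placements: Sequence[ReadPlacementSet],
    template_length: int,
    params: ScoringParams,
    template_id: str = "template",
) -> TemplateScore:
    """Score one template: build the segmentation and instance, solve the
    matching, and record both scores plus the per-segment coverage profile.

    The returned score is re-verified against a direct evaluation of the
    stored matching.
    """
    segmentation = segment_template(template_length, len(placements), params)
    instance = build_instance(placements, segmentation, params)
    matching, score = solve_csm(instance)
    check = matching_cost(instance, matching)
    assert abs(check - score) <= 1e-6 * max(1.0, abs(score))
    profile = coverage_profile(matching, segmentation)
    return TemplateScore(
        template_id=template_id,
        sage_score=score,
        naive_score=naive_score(placements, params),
        matching=matching,
        coverage_profile=profile,
        unmatched_count=len(placements) - len(matching),
        segmentation=segmentation,
    )


def rank_templates(scores: Sequence[TemplateScore]) -> list[TemplateScore]:
    """Ascending by score (lower = better support); ties broken by id."""
    if not scores:
        raise ValueError("need at least one template score")
    return sorted(scores, key=lambda s: (s.sage_score, s.template_id))


def normalize_second_best(scores: Sequence[float]) -> list[float]:
    """Affine-rescale a row of raw scores so the second-best maps to 1 and the
    worst to 0 (the best then maps to a value >= 1).

    Degenerate rows: all-equal scores map to all 1; rows where the
    second-best ties the worst (including two-template rows) fall back to
    best -> 1, worst -> 0.
    """
    if not scores:
        return []
    ordered = sorted(scores)
    worst = ordered[-1]
    second = ordered[1] if len(ordered) > 1 else ordered[0]
    if worst == ordered[0]:
        return [1.0] * len(scores)
    anchor = second if worst != second else ordered[0]
    return [(worst - s) / (worst - anchor) for s in scores]


def profile_tsv(score: TemplateScore) -> str:
    """Coverage profile as TSV: segment start, matched count, expected."""
    lines = ["start\tcount\texpected"]
    for (start, _end), count, lam in zip(
        score.segmentation.boundaries,
        score.coverage_profile,
        score.segmentation.expected_coverage,
    ):
        lines.append(f"{start}\t{count}\t{lam:g}")
    return "\n".join(lines) + "\n"
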