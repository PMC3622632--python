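# sagescore

Coverage-sensitive scoring of predicted genome templates from multi-mapped
short reads.

Given a predicted genomic sequence (a "template") and a set of paired-end
reads mapped to it with *all* candidate locations reported, `sagescore`
assigns the template a quality score by solving a many-to-many min-cost
matching between reads and fixed-length template segments. The objective
combines per-placement alignment costs with convex per-segment penalties for
deviating from the expected read coverage, so templates with wrong copy
number, deleted blocks or swapped repeats are penalized even when every read
still aligns somewhere. The convex case is solved exactly by reduction to a
min-cost integer flow; a brute-force enumerator doubles as a verification
oracle on small instances.

A synthetic-data module generates repeat-rich templates (libraries of
mutually ~90%-identical gene-sized blocks arranged into haplotype
architectures), paired-end reads with substitution errors, and exhaustive
candidate alignments, so the whole pipeline runs without external tools or
data.

## CLI

```sh
# generate a synthetic benchmark (templates, reads, alignments, truth)
sage simulate --config sim.cfg --out sim/

# score one template against a mapped read set
sage score --alignments sim/alignments_template0.sam \
           --template sim/templates.fa --template-id template0 \
           --params params.cfg --out scores/

# score a manifest of (read set, template) pairs into ranking matrices
sage rank --manifest manifest.tsv --params params.cfg --out matrices/

# brute-force optimum of a small serialized instance (verification)
sage oracle --instance instance.txt
```

`params.cfg` is flat `key = value` text; supported keys (defaults in
parentheses): `segment_length` (1000), `unmatched_penalty` (100),
`discordant_penalty` (90), `coverage_cost_kind` (`polynomial`; or `linear`),
`coverage_exponent` (2), `expected_coverage` (optional comma list overriding
the computed per-segment expectation), `mismatch_cost` (30),
`max_mismatches_per_end` (3), `cost_tag` (`ZC`), `insert_mean` (400),
`insert_sd` (40). Unknown keys are rejected.

Alignments are read from SAM/BAM. Each mapped record must carry the per-end
alignment cost in the `cost_tag` SAM tag; proper-pair flags mark concordant
placements (costs of both ends summed), other mapped records are treated as
discordant single-end placements (cost + `discordant_penalty`). The
`sage simulate` output follows these conventions.

`sage score` writes `score.json` / `score.tsv` (both scores, matched and
unmatched read counts), `profile.tsv` (per-segment matched-read counts vs
expectation) and `run_info.json` (parameters and input digests). `sage rank`
writes raw, percent-from-top and second-best-normalized score matrices, the
naive-baseline matrix, and per-read-set winners.

## Library

```python
from sagescore import ScoringParams, score_template
from sagescore.simulator import (
    HaplotypeArchitecture, exhaustive_map, make_block_library,
    render_haplotype, simulate_reads,
)

lib = make_block_library(4, (4000, 6000), identity=0.90, seed=1)
template = render_haplotype(
    HaplotypeArchitecture(("block0", "block1", "block2", "block3"),
                          (200, 200, 200)), lib)
reads = simulate_reads(template, coverage=30, error_rate=0.005, seed=2)
params = ScoringParams()
placements = exhaustive_map(reads, template, params)
result = score_template(placements, len(template), params)
print(result.sage_score, result.naive_score, result.coverage_profile)
```

Lower scores mean better support. Diploid templates are scored by
concatenating the two haplotype sequences into one template.

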