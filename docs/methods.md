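# Methods

This note documents the models and procedures `ovimir` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical and design choices made where the rules left
room.

## Candidate filtering

Hairpin discovery tools score candidates with a probabilistic model of
miRNA biogenesis; the score threshold is chosen empirically as the lowest
cutoff whose estimated signal-to-noise ratio (true:false calls) strictly
exceeds 10:1. `select_score_cutoff` consumes a `(cutoff, snr)` table and
returns that cutoff; the SNR estimation itself (permuted-genome runs inside
the discovery tool) is out of scope.

Retention rules are applied in a fixed order so every dropped candidate
has exactly one recorded reason:

1. `low_score` — novel candidates scoring below the cutoff. Known
   precursors (already present in the reference catalog) are exempt from
   this rule only, their hairpins being considered validated.
2. `low_count` — no mature form reaches 10 reads. The floor is applied to
   the **pooled** total across libraries by default; the narrative this
   reproduces is ambiguous between pooled and per-library, so per-library
   presence (with the same floor) is handled separately in the
   specificity/arm analyses.
3. `repeat` — more than 5 self-genome hits at E < 2·10⁻⁸ landing on
   distinct chromosomal areas. "Distinct areas" is operationalized as
   non-overlapping subject intervals: subject ids of the form
   `chrom:start-end` are merged when they overlap; opaque subject ids each
   count once.
4. `other_ncrna` — any RefSeq/Rfam hit below the screening E-value
   (snRNA, snoRNA, tRNA and similar). No separate threshold is published
   for this screen; the repeat-screen value 2·10⁻⁸ is reused since both
   belong to the same screening step (configurable independently).

## Conservation tiers

Tiers come from miRBase homology hits, counting distinct species whose
best hit passes a tier's E-value threshold:

| tier | rule | default E |
|---|---|---|
| conserved_broad | ≥ 5 species | < 4·10⁻⁹ |
| conserved_narrow | 2–4 species | < 9·10⁻⁵ |
| conserved_single | exactly 1 species | < 2·10⁻⁴ |
| nonconserved | otherwise | — |

The narrow tier requires at least two species so the three conserved
tiers are mutually exclusive (a bare "< 5 species" reading would swallow
the single-species class, which holds both single-species family matches
— e.g. large bovine miR-2284/2285-family homologs — and strong distant
single-species homologs). A candidate whose only support fails every
threshold is non-conserved and its supporting-species set is recorded
empty by definition.

## Nomenclature

Names are deterministic functions of the catalog, independent of input
order (all tie-breaks use genomic coordinates):

* Conserved candidates inherit the name of the closest homolog mature.
  "Closest" uses an ungapped best-offset similarity with the seed region
  (mature positions 2–8) weighted double:
  `score = 2·(seed matches) + (other matches)`, maximized over all
  offsets. This scoring is deliberately simple and isolated
  (`similarity_score`) so it can be swapped.
* Several candidates mapping to one homolog name: if their matures are
  identical the name is shared with `-1`, `-2` suffixes; otherwise
  progressive letters `a`, `b`, … are appended, both in coordinate order.
* Non-conserved candidates get `oar-miR-N1…Nk` in coordinate order; a
  group encoding one identical mature shares its number with `-1`, `-2`.
* Family labels strip the species prefix, arm suffix, duplicate index and
  trailing variant letters (`oar-miR-2285la → miR-2285`); a duplicate
  index is only stripped when the remainder still ends in the family
  number, so `miR-2281` is not truncated to `miR`.

## isomiR taxonomy

Each read overlapping its mature interval gets exactly one category.
End offsets are computed as `read start − mature start` (negative = 5′
extension) and `read end − mature end` (positive = 3′ extension). An
extended end is *non-templated* iff at least one extending base disagrees
with the hairpin at its aligned position (bases aligned past the hairpin
ends count as non-templated; truncations and shifts within the hairpin
are always templated). Internal substitutions are mismatches within both
the read and the hairpin body, excluding extension bases.

Precedence (making the categories exclusive, as fraction reports require):
substitutions → `polymorphic`; both ends variant → `both_ends_*` (mixed
templated/non-templated collapses conservatively to
`both_ends_nontemplated`); one end variant → `{non}templated_{5p,3p}`;
else `reference`. A read is seed-affecting iff its 5′ offset is nonzero
or a substitution falls in positions 2–8. Reads not overlapping any
mature (star/loop reads) are excluded from distributions and tallied
separately. Dominant-form calls group reads by (start, sequence), rank by
summed count across libraries, and break ties reference-first then by
lexicographically smallest sequence.

Pooled fractions are count-weighted over both libraries; per-library
fractions are also reported (the two weightings are not interchangeable,
and published pooled percentages are generally not exactly re-derivable
from per-library percentages without the underlying totals).

## Arm preference and grouping

An arm is expressed in a library when its count reaches the same floor
used in filtering (≥ 10; a strict-greater option exists because the
source narrative uses both "> 10" and "below 10 removed" phrasings — the
≥ reading keeps the two rules consistent). The dominant arm has the
strictly greater count; ties go to 5p, reflecting the observed genome-wide
5p majority (documented as arbitrary). An arm switch is flagged when both
libraries have a dominant arm and they differ; the count is symmetric in
the library order. Same-mature grouping is exact string grouping of
canonicalized (uppercase, U-form) mature sequences.

## Genomic distribution

Specificity: a precursor is present in a library when any mature reaches
the floor there; the classes A-only / B-only / both partition the present
set, and totals are reported for precursors and matures separately (the
two rows of the summary table). Clusters: precursors sorted by
(chromosome, strand, start) are chained while the gap from the running
envelope end to the next start is < 10 kb; chaining is transitive (long
polycistronic runs form one cluster), the gap is measured
boundary-to-boundary (the stricter conventional reading of "inter-miRNA
distance"), overlapping precursors chain, and a cluster needs ≥ 2
members. Densities are `count / (chromosome length / 10⁶)`, kept
unrounded and also rendered at 2 decimals.

## Quantification

Size factors use the median-of-ratios estimator for experiments without
replicates: for library *j*, the median over features positive in every
library of `count_ij / (∏_k count_ik)^(1/m)`. Fold change divides
normalized counts with **no pseudocount** by default (a configurable
pseudocount exists for degenerate synthetic cases): a zero denominator is
flagged infinite, a zero numerator gives 0, and 0/0 is NaN. Dispersion
modelling and significance testing are deliberately out of scope — only
fold changes are produced. qRT-PCR: an assay is expressed iff Ct is
strictly below 35 (35.000 is not expressed); `ΔCt = Ct_assay − Ct_U6` and
`RQ = 2^−ΔCt`, so the control has RQ 1 and RQ is strictly decreasing in
Ct. Only per-assay ΔCt against the plate's U6 control is implemented; the
bundled validation panels carry one U6 per panel.

## Synthetic data generator

The generator emulates the *structure* of a two-library discovery
experiment with every downstream quantity planted and recorded in a
ground-truth manifest. Defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| specificity quotas | 12 / 76 / 84 | LV-only / GL-only / shared novel precursors |
| two-mature quotas | 7 / 39 / 46 | per class, giving 19 / 115 / 130 mature forms |
| tier quotas | 112 / 10 / 29 / 21 | broad / narrow / single / non-conserved |
| duplicate pairs | 13 | precursor pairs sharing one mature sequence |
| novel clusters | sizes (3,3,3,2,2,2,2) | 17 precursors in 7 clusters, gaps 0.5–9 kb |
| arm switches | 5 | shared two-mature precursors with opposite dominance |
| 5p dominance | 0.64 | probability the 5p arm dominates |
| isomiR proportions | reference 0.575, t3′ 0.18, nt3′ 0.105, polymorphic 0.085, t5′ 0.05, rare classes 0.005 | per-read multinomial, near the observed pooled distribution |
| in-band length rate | 0.9093 | read mass with mature length 20–22 nt (band 18–24) |
| read depth | lognormal(4.3, 0.9), floor 12 | per mature per present library |
| known precursors | 20 (3 clustered) | score-rule-exempt catalog entries |
| doomed candidates | 3+3+4+6 | one per drop rule, for filter accounting |

Mechanics worth knowing:

* Reads are **forward-edited** from the reference mature (templated edits
  copy hairpin bases, non-templated additions draw A/U-biased bases that
  differ from the template, polymorphic reads substitute one internal
  base), so mismatch annotations are exact by construction and every
  read's true category is recorded.
* The 18–24 nt read-length rate is realized by stratification: mature
  lengths are 20–22 nt except for length-sharing groups assigned
  out-of-band (15/16/26/27 nt) in shuffled order until the out-of-band
  read mass reaches 1 − 0.9093 of the total. This concentrates the
  realized read-level rate near the target; a per-precursor Bernoulli
  draw would leave it fluctuating by several percentage points.
* Hairpins are random sequence with the star arm biased to the reverse
  complement of the mature (three substitutions); no secondary-structure
  prediction or thermodynamics. Star reads (~3 % of a single-mature
  precursor's depth) exercise the star/loop exclusion path.
* Conservation hits realize each tier's species-count and E-value ranges;
  the homolog catalog contains one mutated copy (two non-seed
  substitutions) of each conserved candidate's mature, with two planted
  shared-homolog pairs exercising letter suffixes.
* Everything derives from one `numpy` PCG64 generator: a fixed seed gives
  byte-identical output files.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequencing error and quality scores, adapter
artifacts, genome-wide mapping ambiguity (reads are pre-assigned to their
hairpin), real hairpin thermodynamics, biological inter-library dispersion
beyond the planted structure, and cross-mapping between paralogous
precursors. Tests demonstrate that the *rules* are implemented correctly
and recover planted structure, not that the rules are biologically optimal.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open internally; BED is emitted natively;
  T/U interchange on input with uppercase U-form canonical.
* Read totals are always derived from per-library counts, never stored.
* Distribution fractions must sum to 1 within 10⁻⁹ per library.
* Empty inputs are valid where meaningful (empty precursor table → empty
  but valid report; empty hit list → non-conserved; empty BED); empty
  read stacks and missing controls raise explicit errors.
* Statistical recovery tests (isomiR proportions, length-band rate)
  assert exact agreement with the generator's realized tallies, plus
  agreement with the configured rates within 3 binomial standard errors
  at the 10⁴-read scale the recovery property is stated for — the default
  scenario generates ~7·10⁴ reads, at which scale the generator's own
  multinomial draw can legitimately sit several SE from its configured
  parameter.

## Problem sizes

The default scenario (208 candidates, ~75,000 read units, ~2,800 stack
rows) runs the full pipeline in about two seconds; oracle-equivalence
suites use 50-precursor layouts and ≤ 30-read stacks and run in well under
a second. These sizes were chosen so the whole test suite and the
acceptance script complete in seconds while every planted structure
(quotas, clusters, pairs, switches, tiers) is still recovered exactly.
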