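# Methods

## The enrichment model

For one marker list against one detected universe, condition on the 2×2 table

|            | increased | not increased |
|------------|-----------|---------------|
| in list    | k         | n − k         |
| out of list| U − k     | N − n − (U − k) |

where N is the number of detected features, U the number called increased,
and n the list's detected size.  Two statistics are reported:

- **Fold enrichment** FE = (k/n) / b, with background b = U/N by default.
  The denominator is the *detected* list size, not the raw size: the only
  fully worked published example of this statistic (28/55 = 50.9% against a
  3.48% background, "more than 14 times" chance) uses detected counts.  A
  caller can override b with a printed constant (0.0348 for transcripts,
  0.0858 for proteins) to reproduce published folds exactly even when the
  direction calls are re-derived.
- **Fisher exact p**, one-sided (`greater`) by default, since the hypothesis
  is directional overrepresentation; two-sided is available by flag.  The
  hypergeometric tail is computed in log space (`gammaln` + `logsumexp`), so
  tables with totals in the tens of thousands are exact to machine precision
  rather than underflowing.  Unit and acceptance tests check the
  implementation against exhaustive integer enumeration (all tables with
  total ≤ 60, 1e-12 tolerance) and against an independent library
  implementation.

No cross-list multiple-testing correction is applied in the battery: each
list is a separate hypothesis reported with its own p, as is standard for
small curated batteries.  BY correction applies only within cell-type
enrichment (below).

### Universe and join keys

Everything is conditioned on the *detected* universe.  Transcript universes
join marker lists on gene ids (published lists are gene-keyed; a gene counts
as increased if any of its transcripts is); protein universes join on the
protein-isoform id, with gene→isoform conversion done by the identifier map
at the encoding-gene level — any detected protein product of a list gene
matches, never a specific isoform.  Protein mapping starts from the list's
raw gene set: which isoforms survive is decided by detection in the protein
universe itself, not by the transcript-level filter.

### Direction calls

The focal dataset's increased/decreased calls are either taken verbatim from
a supplied column ("as-given" mode — the right choice when reproducing a
published universe whose exact significance criteria are unstated) or derived
as adj_p ≤ α (default 0.05) with |log2FC| ≥ a configurable floor (default 0;
a feature with log2FC exactly 0 is never directional).

## Cell-type enrichment

For a query gene list against a cell-type marker database, each term is
scored by the same 2×2 construction (query × term markers over the gene
universe), fold enrichment is the query's overlap fraction over the term's
share of the universe, and p-values are Benjamini–Yekutieli adjusted across
all terms (BY rather than BH because marker sets overlap heavily, i.e.
arbitrary dependence).  Terms with adjusted p < α are ranked by fold
enrichment descending; ties break by smaller adjusted p, then lexical term
order, so output is deterministic.  The published "102 significant terms /
17-of-20 macrophage" result depends on an external database version and is
deliberately not a test target; the planted-term simulation validates the
machinery instead.

## Immunoblot quantification rule

Densitometry signals are divided lane-wise by the loading-control reference,
both groups scaled so the control mean is 1, and group means compared by a
two-sided Student t test (pooled variance as literally named; Welch by flag)
on log2-transformed values — the log transform stabilizes the variance of
ratio data.  A comparison is significant only when p < 0.05 AND the raw-scale
fold change is ≥ 1.25 or ≤ 0.8.  The fold criterion is applied on the raw
ratio scale (equivalent to a log2 threshold; either convention gives the same
calls).

## Synthetic data: what it emulates and what it does not

Defaults state the emulated world: 10,903 detected transcripts, 3.5%
increased, 1.6% decreased; a battery of five marker lists whose sizes and
planted enrichments ρ are those implied by the published table counts
(55/14.65, 159/9.77, 36/12.79, 132/8.72, 31/19.49), including one
union-of-two-studies list and one intersection-of-two-studies list; a protein
universe with an 8.58% increased fraction.

Generator mechanics:

- Direction flags are drawn i.i.d. per feature; p / adjusted-p / log2FC
  columns are then drawn consistently with the flags at α = 0.05, so
  re-deriving calls from the statistics reproduces the planted flags exactly.
- List members are sampled from the realized universe such that each member
  is increased with probability min(1, ρ · frac_up); study tables carry
  statistic columns that pass the study's selection rule for members and fail
  it for decoy rows, so rule application recovers membership exactly.  Each
  list also plants a few genes absent from the universe so the detection
  filter is exercised.
- Each gene gets 1 + Poisson(λ − 1) protein isoforms (λ = 1.5 — fly genes
  typically encode a small number of annotated isoforms); each isoform is
  detected in the protein universe with probability 0.5 (proteomics detects
  far fewer features than RNA-Seq; ~16k isoforms × 0.5 gives a universe of
  the same order as a deep fly-head proteome) and detected isoforms are
  increased with probability 0.0858 (decreased 0.04, a modest value chosen
  since no published figure exists for it).
- All streams derive from one master seed via per-component keys
  (CRC32-of-name), so regenerating one file never perturbs the others, and
  identical seeds yield byte-identical bundles.

The generator plants direction *calls*, not counts: it does not simulate
reads, dispersion, library-size effects, correlated co-regulation, or
isoform-level quantification noise.  A green recovery test therefore
establishes that the pipeline's set algebra and statistics are correct under
the stated marginal model — not that the upstream DE model would behave on
real data.

`universe_from_counts` / `marker_list_from_counts` are the degenerate,
deterministic corner of the generator: a universe and list built to exact
summary counts.  Overlap statistics depend on the 2×2 counts only, so these
reproduce any published row exactly.

## Numerical and design choices

- Rule inequalities follow the source tables typographically: ≥ for FC and
  log2FC thresholds, ≤ for adjusted p, strict > for emPAI.
- FC rules act on the raw fold-change scale and log2FC rules on the log
  scale; there is no silent conversion.
- Identifier matching is exact and case-sensitive after whitespace trimming;
  FlyBase-style ids are case-stable and silent case-folding hides data errors.
- Duplicate genes within a study table are deduplicated (logged) before rule
  application; duplicate feature ids in a universe are an error.
- The two-sided Fisher test uses the standard "no more probable than
  observed" convention with a 1e-7 relative log-space tolerance.
- Degenerate cases: an empty list (after detection filtering) reports fold 0
  and p 1; a 2×2 with an empty margin reports p 1; an odds ratio with a zero
  denominator is ∞ when the numerator is positive.
- BY adjustment is the standard step-up with harmonic-sum inflation,
  delegated to a stock statistical library and verified in tests against the
  textbook formula; adjusted values are clipped to 1 and returned in input
  order.

## Known limitations

- Transcript universes with many-to-one transcript→gene structure are scored
  with gene-level overlap counts against a feature-level universe size; when
  multiplicity is high the 2×2 margins are approximate.  The synthetic
  transcript universe is one-transcript-per-gene, where the two coincide.
- The published "~7- to 18-fold" narrative range cannot be regenerated
  exactly from any printed counts under either denominator convention; this
  package reports the detected-denominator folds (~8.7–19.5 for the same
  rows) and exposes the background override for the alternative.
- Immune subclassification (humoral vs cellular) is a curation overlay file,
  not an algorithm — the original assignment was manual.
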