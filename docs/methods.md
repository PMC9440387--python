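# Methods

This note documents the models, defaults and numerical choices behind
`maternalome`, and what the synthetic-data experiments do and do not show
about real data.

## Data model

A dataset is a protein × stage × replicate array of non-negative LFQ-style
intensities.  **Zero and absent are both "missing"**: in label-free MS a
zero LFQ intensity means the protein was not detected in that sample, and
every downstream rule in this pipeline is detection-based, so the two cases
are deliberately not distinguished.  Stage order is explicit metadata
(default PN, 2C, 4C, 8C, MO, BL) and every output follows it regardless of
input row order.

Protein identity across datasets is the **case-folded gene symbol**
(`Fbxw24`, `FBXW24` → `fbxw24`), optionally with isoform-suffix stripping.
Datasets built against different sequence databases (Swiss-Prot, IPI,
UniProtKB) can only be compared at this level; accession-level mapping is
out of scope, and collisions created by case-folding are reported rather
than silently merged.

## Quantification filter

A protein is *quantified* when there are at least `min_stages` stages at
which it was detected in at least `min_replicates` replicates.  The default
is `min_replicates = 3` of 3 — the strict reading of "more than two
biological replicates" for a triplicate design — with `min_replicates = 2`
available because the lenient reading ("at least two") is common practice.
The filter is monotone in both thresholds (relaxing either can only grow
the retained set), a property the test suite asserts against brute-force
enumeration.

## Replicate aggregation and standardization

Default aggregation is the **mean of log2 intensities** over non-missing
replicates.  Correlation screening and clustering operate on relative
trajectories, and log-scale means damp the multiplicative outliers typical
of LFQ; `median_log2` and `mean_raw` are provided because the choice is not
forced by anything upstream.  A stage with no observation stays missing and
propagates into pairwise-complete correlation rather than being imputed.

Profiles are standardized per protein to mean 0 and sample standard
deviation 1 (divisor n − 1) over observed stages.  Constant profiles raise
a *degenerate* flag and are excluded from clustering and screening instead
of emitting infinities.

## Fuzzy c-means

Written from scratch because the membership matrix is the scientific
output (profiles are colored by membership, and cluster calls use a
membership cutoff), not just the hard labels:

- objective J = Σᵢ Σₖ u(i,k)^m ‖xᵢ − cₖ‖², Euclidean distance;
- alternating updates (centers as u^m-weighted means, memberships as
  inverse-distance ratios raised to 2/(m−1)); a point at exactly zero
  distance from a center takes membership 1 there;
- fuzzifier default m = 2.0, the standard choice; c defaults to 10 in the
  pipeline configuration (the cluster count used for full-proteome
  trajectory atlases) but recovery experiments use the number of planted
  archetypes;
- convergence when the objective drops by < 1e−6, cap 300 iterations;
- initialization is a seeded random membership matrix; **5 restarts** are
  run and the lowest final objective kept, since FCM is initialization
  sensitive; all restarts derive from one seed via seed-sequence spawning;
- the per-iteration objective trace is recorded and checked non-increasing
  (1e−9 slack for float round-off) every time a model is constructed.

Hard assignment is argmax membership with ties broken toward the lowest
cluster index; `passes_cutoff` requires the top membership to be *strictly*
above the cutoff (default 0.5).

Hierarchical linkage (euclidean or 1 − Pearson; average/complete/ward) and
PCA are thin wrappers over scipy/numpy SVD; PCA defines explained-variance
fractions as 0 for zero-variance input.

## Anchor-correlation screen

Pearson r is computed over pairwise-complete stages; fewer than 3 complete
pairs or zero spread yields an *undefined* marker (NaN) that propagates to
an `undefined` strength class instead of raising.  The two-sided p-value
uses the exact transform t = r√((n−2)/(1−r²)) with n − 2 degrees of
freedom; |r| = 1 maps to p = 0 by continuity.  For the six-stage design
(df = 4) this reduces to the closed form p = 1 − 1.5|r| + 0.5|r|³, which
the tests verify both against `p_from_r` (to 1e−10 across an r grid) and
against numerical integration of the t density.

A **strong** correlation is |r| ≥ 0.70 with p ≤ 0.05 (both thresholds
inclusive).  Per-protein verdicts combine the per-anchor classes under a
configurable rule — `all` (default: strong with a consistent sign against
every anchor), `any` (strong against at least one; conflicting signs
exclude the protein with reason `sign_conflict`), or `mean_profile`
(correlate against the standardized mean anchor trajectory).  The rule is
explicit because collective phrasing like "correlated with the SCMC" does
not pin it down.  p-values are reported unadjusted, as is conventional for
this screen; a Benjamini–Hochberg column can be added downstream but is
not applied by default.

The published Fbxw-family vs SCMC correlation table bundled in
`maternalome.reference` serves as a worked-example fixture: recomputing p
from each printed r at n = 6 reproduces the printed p at four decimals for
37 of 48 originally checked cells (102 cells are bundled), the exceptions
differing by one unit in the fourth decimal because the printed r is itself
rounded.  The six cells exposed as `WORKED_EXAMPLES` all reproduce exactly.

## Fate classification and consensus

`exclusive_regions` partitions the union of k named sets into the 2^k − 1
exclusive regions (asserted to be a partition on every call);
`fate_classify` is the three-set specialization with fixed region names
and biological aliases — MII ∩ PA \ ZY is `degradation_escape`,
MII ∩ PA ∩ ZY is `core_maternal`, MII ∩ ZY \ PA is
`persistent_after_fertilization`.  Aliases are surfaced in outputs but
never participate in the set logic.  Proteins outside all three sets get no
assignment (Venn semantics).  Cross-dataset consensus of signed verdicts is
`strict` (same sign in every dataset; antitone in the number of datasets)
or `majority`; sign conflicts are excluded with a logged reason.

## Synthetic data: what it emulates and what it does not

The generator mirrors a triplicate six-stage LFQ time course:

- **archetypes** on the log2 intensity scale (base ≈ 23–26, i.e. realistic
  LFQ magnitudes): `maternal_decay` (monotone fall, ~4 log2 units PN→BL),
  `blastocyst_rise` (flat through 8C, jump at MO/BL), `mid_peak`
  (interior peak);
- **noise**: additive Gaussian on log2 intensity per replicate
  (multiplicative log-normal on the raw scale), the standard LFQ error
  model; default σ = 0.5 log2 units, recovery experiments use σ = 0.3;
- **dropout**: missing completely at random, default rate 0.1, with an
  optional intensity-dependent mode (logistic in the log2 cell mean) that
  reproduces the low-abundance dropout typical of LFQ; MCAR is the default
  because it keeps the recovery oracles exact;
- **planted anchor modules**: a protein's mean trajectory is rebuilt as
  r·z(anchor) + √(1−r²)·z(g) with g Gram–Schmidt-orthogonalized against
  the anchor, then mapped to base 24 + 1.5·z log2 units, making the
  noiseless correlation *exactly* the target (verified to 1e−9);
- **tri-study draws**: a seeded multinomial over the seven Venn regions,
  emitted as three id sets plus per-protein truth.

The screen-recovery instance uses 5 anchors sharing one module trajectory
(the SCMC co-expresses tightly in all three embryo datasets), 50 planted
proteins split evenly between +0.9 and −0.9, and 450 nulls with iid
standard-normal stage profiles.  σ = 0.5 and dropout 0.1 as global defaults
are calibration choices, documented here, not measured values.

What passing these experiments does **not** show: the generator has no
peptide-level identification, no shared-peptide ambiguity, no
between-stage intensity normalization issues, no batch structure, and its
nulls are independent of the anchors — real proteomes have pervasive
co-expression, so a real screen's false-positive rate against the "not
biologically related" null is necessarily higher than the MCAR-simulated
one.  Recovery results validate the *implementation*, not a claim about
error rates on real embryo data.

All randomness flows from one explicit seed through numpy seed-sequence
spawning, so sub-simulations are independently reproducible and everything
is byte-deterministic given (parameters, seed).

## Problem sizes

Recovery experiments run at 500 proteins × 10 seeds (screen) and
300 profiles × 10 seeds (clustering); oracle checks use 100 random
instances with up to 6 sets over up to 500 ids, or up to 120 proteins per
detection table.  These sizes give stable means (±0.02 on the recovery
rates across seeds) in seconds on one core; they are desk-scale stand-ins
for a ~2,000-protein proteome and scale linearly if raised.

## Known limitations

- Gene-symbol matching cannot resolve paralogs that share a symbol across
  database versions, and case-folding can merge distinct ids (reported,
  not fixed).
- Pairwise-complete correlation with n recorded per pair means p-values
  across proteins are not all at the same n; records carry n so downstream
  filtering can enforce a floor.
- FCM restarts make the returned model the best of 5, not a global
  optimum; permuting input rows can relabel clusters (the objective is
  invariant, labels are not).
- The pipeline's `fate` stage classifies simulated detection sets when run
  in demo mode; wiring three real candidate tables through
  `consensus_candidates` and `fate_classify` is the intended production
  path.
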