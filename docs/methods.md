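# Methods

## The quantity: side-chain element content

For a protein sequence of cleaned length L with residue counts p_i, the
content of element E (one of C, H, N, O, S) is

    [E] = sum_i w_i(E) * p_i / L,

where w_i(E) is the number of atoms of E on the side chain of residue
type i.  The backbone (N–Cα–C=O), identical for every residue, is
excluded, as are the free termini of the peptide: the content measures
only the variable part of the molecule on which composition-level
selection can act.  w_i is derived from the free amino-acid molecular
formula minus H2O (peptide bond) minus the chain backbone C2H2NO;
proline's ring is charged entirely to the side chain under the same
subtraction (C3H5).  Glycine's side chain is a single hydrogen, so
[O]=[C]=0 for poly-glycine; the maximum side-chain oxygen is 2 (Asp,
Glu) and the maximum carbon 9 (Trp), which bound any sequence's [O] in
[0, 2] and [C] in [0, 9].

A proteome's content is the unweighted mean of per-sequence contents —
each protein counts once regardless of length, so a handful of titin-like
giants cannot dominate the summary.

Non-standard letters (B, Z, J, X, U, O, `*`, gaps) are dropped before
computation and L is the cleaned length; the per-sequence dropped count
is kept on the profile.  Selenocysteine is *not* remapped to cysteine by
default, because that would silently alter sulfur content.  An empty or
all-invalid sequence is an error, never a silent zero.

## Expression scores from categorical staining

Antibody-based pathology atlases report, per protein and sample, a
staining intensity (negative / weak / moderate / strong; "medium" is
accepted as a synonym of moderate) and a stained-cell fraction (<25%,
25–75%, >75%), with "−" marking proteins not annotated in a sample.  The
default numeric mapping is the product of an intensity weight {0, 1, 2, 3}
and a fraction weight {1, 2, 4}.  Its maximum, 12, coincides with the
conventional high-expression score threshold (score ≥ 12), which is why
this product form was chosen over alternatives such as the 0–300 H-score;
the mapping is a plain config object and every downstream stage depends
only on the numeric matrix, so an alternative mapping is drop-in.

Per-protein mean scores are taken over non-missing samples only, and a
protein missing in every sample is deleted rather than scored 0.  High/low
expression groups are selected by top/bottom fraction (count = ceil(f·n),
so small proteomes still yield non-empty selections) or by inclusive score
thresholds (≥ 12 high, ≤ 0.1 low).  Ties at a fraction boundary are broken
by protein id, ascending — an arbitrary but deterministic rule, echoed in
output headers, so runs are reproducible across platforms.

## Differential expression screen

Each protein's case samples are compared with its control samples via

* a fold gate: log2((case + c)/(control + c)) with pseudocount c = 0.1 by
  default (the scale of the low-expression threshold), guarding zero
  control scores;
* a moderated two-sample t: the pooled variance s² (residual df d) is
  shrunk toward an empirical-Bayes prior, s̃² = (d0·s0² + d·s²)/(d0 + d),
  and the statistic referred to t with d0 + d df.  With d0 = 0 this is
  exactly the ordinary pooled t-test; with d0 → ∞ the prior variance is
  used alone (normal reference).  A protein with zero shrunken variance is
  degenerate: equal means give (0, 1), separated means (±∞, 0), flagged as
  such rather than erroring;
* the prior (d0, s0²) is fitted by the standard method of moments on
  log s²: with e = log s² − ψ(d/2) + log(d/2), the excess of Var(e) over
  ψ′(d/2) equals ψ′(d0/2), inverted by a Newton iteration on the trigamma
  function.  Exactly-equal variances return (∞, the common value); an
  observed dispersion at or below the sampling minimum returns
  (∞, exp(mean e)).  Fewer than 10 positive variances is an error that
  directs the caller to the unmoderated d0 = 0 mode.  When the screen
  estimates the prior itself it uses proteins at the modal residual df
  (missing values make df vary across proteins);
* BH-FDR q-values across the screened proteins, and the combined call:
  up if log2 ratio > 1 ∧ p < α ∧ q ≤ Q, down if log2 ratio < −1 with the
  same significance gates, none otherwise.  Defaults α = 0.05, Q = 0.01,
  fold cutoff 1.  The down cutoff is −1, the mirror of the up cutoff: a
  literal "< 1" rule would classify every non-up protein as down.  Both
  significance gates are kept independent even though the FDR gate
  usually dominates.

The two control proteomes are screened as one two-sample comparison
(12 case values vs 2 control values per protein) by default.

## Rank tests and the percent-difference statistic

Group comparisons of element content use the two-sample Mann-Whitney U
(equivalently the unpaired Wilcoxon rank-sum; there is no pairing
structure here), with U = #{(a, b): a > b} + ties/2 via midranks.

* Exact path (default for n_a + n_b ≤ 12): full enumeration of the
  C(n, n_a) group assignments of the pooled values — a permutation null
  that remains exact under ties.  Two-sided p = 2·min(P(U ≤ u), P(U ≥ u)),
  capped at 1.
* Approximate path: normal approximation with tie-corrected variance,
  continuity correction, and a one-term Edgeworth kurtosis correction.
  The tie-free U null is symmetric but platykurtic with exact excess
  kurtosis γ₂ = −(6/5)(n_a² + n_b² + n_a·n_b + N) / (n_a·n_b·(N + 1)),
  N = n_a + n_b (verified against full enumeration for all N ≤ 12); the
  corrected tail is Φ(z) − φ(z)·(γ₂/24)(z³ − 3z).  On continuous data
  with both groups ≥ 2 and N in [6, 12] the worst absolute deviation from
  the exact p is 0.033 (exhaustive scan); a plain continuity-corrected
  normal reaches 0.088 on the same domain.  Heavily tied tiny samples
  (e.g. [1,1] vs [1,4], whose permutation null is two-point) are outside
  any smooth approximation's reach and are always served by the exact
  path.

The headline effect size is the percent difference of group means,
100·(mean_a − mean_b)/mean_b — the reference group (denominator) is the
second group, e.g. (up − down)/down.  It is reported to one decimal and
undefined (NaN, not an error) in a comparison whose reference mean is 0.
Carbon is computed alongside the element of interest in every comparison:
as the most abundant side-chain element it serves as a negative control
for composition-wide artifacts (a real oxygen signal should not come with
a matching carbon signal).

## Localization and over-representation

DEP-encoding genes are counted per karyotype chromosome ({1..22, X, Y,
MT}; anything else "unplaced"), case-folded and deduplicated by gene so a
gene encoding several screened proteins counts once; genes absent from
the annotation are tallied as "unlocated", preserving the invariant
located + unlocated = unique input genes.  Annotation comes from a
2-column TSV or from GFF3 gene features (seqid + first of gene_name /
Name / gene / ID).

Gene-set enrichment of the discrete up and down lists is hypergeometric
over-representation: p = Σ_{k′≥k} C(K,k′)·C(N−K, n−k′)/C(N,n) with
BH-FDR across sets.  This is a deliberate stand-in for ranked
permutation-based GSEA, which is out of scope: enriching two discrete
gene lists against fixed pathway collections *is* an over-representation
task.  The default universe is the set of genes scored in the run — the
detectable background — not the whole genome; pathway membership must be
supplied as GMT (no live database queries).

## The synthetic study generator

The generator emulates the structure, not the content, of a pathology
atlas analysis: 13,000 proteins, 12 single-patient case samples, 2
single-sample controls, 4×3 categorical annotations with ~5% missing
entries, ~2% planted up-regulated and ~6% down-regulated proteins
(matching the scale of DEP yields such screens report).

* **Composition.** Per-protein residue frequencies are Dirichlet draws
  centred on human-like amino-acid frequencies with concentration 200,
  giving a between-protein [O] spread (sd ≈ 0.05) comparable to real
  proteome-wide distributions; sequence length is uniform on
  [100, 1000] and residues are i.i.d. from the protein's composition.
* **The planted oxygen signal.** Oxygen-bearing residue weights
  (S, T, Y, D, E, N, Q) are multiplied by (1 + δ) and renormalised for
  up-class proteins and for null proteins with high baseline expression
  (latent ≥ 10 of 12, ~10% of nulls), so the oxygen–expression
  association exists in cases and controls alike, mirroring the premise
  that selection acts on the composition of highly expressed proteins
  rather than on transient state.  A (1+δ) tilt changes [O] by the
  factor (1+δ)/(1+qδ), q ≈ 0.37 the summed frequency of oxygen-bearing
  residues; the default δ = 0.05 therefore plants a ~3% relative [O]
  difference — the magnitude of the up-vs-down contrast the emulated
  study design is built to detect.
* **Expression.** Each protein has a latent score in [0, 12]: null
  proteins share one baseline U(1, 11) across conditions; up proteins
  have case U(9, 12) vs control U(0, 1.5); down proteins the mirror.
  Each sample adds Gaussian noise (sd 1.5) to two independent copies of
  the latent, binned into intensity (edges 1.5, 4.5, 9) and fraction
  (edges 4, 9).  Two noised copies, not one, so the full 4×3 grid is
  exercised and discretized scores retain within-protein variation — at
  sd 1.5 the moderated-t screen is calibrated (null p < 0.05 fraction
  ≈ 0.05) despite the discreteness.  With sd 0 the mapping is
  deterministic: an up protein scores (strong, >75%) in cases and
  (negative/weak, <25%) in controls.
* **Genome and gene sets.** Chromosomes are drawn with human-like gene
  count weights; up/down-class proteins are never placed on Y, emulating
  the observed absence of differential genes from the male-specific
  chromosome (plausible when case tissue donors include females and Y
  carries few genes).  Gene sets are random draws plus two planted sets
  enriched in up/down genes so the enrichment stage has signal.
* All randomness flows from the single config seed through named
  `numpy` generators; identical configs produce byte-identical bundles.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: antibody cross-reactivity and batch effects,
homology and domain-sharing between proteins (sequences are independent),
pathway-correlated expression, real karyotype gene content, and the
actual magnitude/shape of the atlas score distribution.  Recovery of the
planted tilt demonstrates the pipeline's correctness and power under its
own assumptions, not the biological finding itself.

## Numerical and design choices

* Problem sizes in the test-suite: the oracle equivalence check uses
  1,000 random sequences; null calibration 2,000 proteins; end-to-end
  power 100 replicates at n = 3,000 with the 12v2 design; the run-from-
  scratch report uses the full 13,000.
* Exact/approximate rank-test switch at n_a + n_b = 12.
* Trigamma inversion: Newton iteration from x = 0.5 + 1/y, tolerance
  1e-10; closed-form guards for very large/small arguments.
* top-k tie-break: id-ascending; boundary thresholds inclusive on both
  ends.
* BH-FDR delegates to `statsmodels` (step-up with enforced monotonicity);
  hypergeometric tails to `scipy.stats.hypergeom`; FASTA parsing to
  Biopython.
* Degenerate inputs: empty groups, empty proteomes, empty annotation,
  lists outside the universe, out-of-range p-values, and vocabulary
  violations are all explicit errors carrying the offending row or name.

## Known limitations

* The moderated screen assumes a simple two-group design; no contrasts,
  sample weights, or variance trends.
* The Edgeworth-corrected approximation uses the tie-free kurtosis with
  the tie-corrected variance; under extreme ties at small n only the
  exact path is trustworthy (and is the default there).
* With only 2 control samples the per-protein control variance is nearly
  uninformative; the screen's power rests on variance moderation, and the
  call set is sensitive to the FDR gate Q.
* Chromosome assignment and gene sets are synthetic conveniences; no
  linkage or pathway biology is represented.
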