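# Methods

## The problem

Sequence-liability annotation is a staple early step in antibody
engineering: short amino-acid motifs — deamidation (NG, NS, …),
isomerization (DG, DS, …), fragmentation (DP, TS), Trp/Met oxidation,
N-linked glycosylation sequons (N-X-S/T, X ≠ P), unpaired cysteines and
integrin-binding motifs — mark positions at risk of chemical modification
that can shorten shelf-life or impair binding.  Motif annotation alone is
strongly over-predictive: almost every variable domain carries several such
motifs.  `ablint` therefore pairs a codified liability reference with three
*low-risk flags* that mark hits which are plausibly benign:

* **germline** — the motif exists at the identical IMGT position, with
  identical residues, in a human germline V or J segment;
* **therapeutic** — the (motif, IMGT start) occurs in strictly more than 5%
  of chains of a marketed-therapeutic panel;
* **surface** — every motif residue is buried (relative solvent-accessible
  surface area at or below 7.5%) in a paired-Fv structural model.

A liability is *removed* by a flag combination iff any applied flag marks
it benign; a sequence *remains* iff it still carries a non-benign hit.

## Detection model

Chains are consumed pre-numbered in the IMGT scheme (positions 1–128,
conserved cysteines at 23 and 104); numbering itself is delegated to
external tools and read from ANARCI-style CSV or AIRR-Rearrangement TSV.
Region boundaries are the standard IMGT delimitation (FR1 1–26, CDR1 27–38,
FR2 39–55, CDR2 56–65, FR3 66–104, CDR3 105–117, FR4 118–128); insertion
codes inherit the region of their base number and keep input order, since
long-CDR3 insertion conventions differ between numbering tools.

Motif adjacency is defined on polypeptide order, not IMGT numeric
adjacency — chemistry acts on consecutive residues and numbering gaps are
notation.  CDR-scope motifs are reported under an *inclusive* policy
(≥ 1 matched residue in a CDR), which captures boundary liabilities that
straddle a framework/CDR junction; a *strict* policy (all residues in a
CDR) is available as configuration.  Overlapping matches of different
reference entries are all reported independently (NGS yields both an NG
deamidation hit and an NGS sequon hit); a double motif such as NGNT counts
as two hits.  The pattern dialect is deliberately tiny — literals,
bracketed classes, one-level negation, top-level alternation, no
quantifiers — so every pattern has a finite expansion and the compiled
matchers can be tested exhaustively against it.

Missing-cysteine hits have no position; they therefore have no surface
class (unknown) and receive `False` for the sequence flags rather than
being matchable.

## Flag semantics and parameters

| parameter | default | meaning |
|---|---|---|
| `therapeutic_threshold` | 0.05 | panel frequency must be strictly greater |
| `exposure_threshold` | 0.075 | relative SASA strictly greater ⇒ exposed |
| `germline_mode` | `assigned` | consult the chain's top V/J (`any`: all pairs) |
| `partial_policy` | `not_benign` | partially buried motifs are not low-risk |
| SASA probe radius | 1.4 Å | water probe |
| SASA points/atom | 960 | deterministic golden-spiral lattice |

Germline matching requires exact (number, insertion) and residue identity
for every motif residue; the flag asserts the motif itself exists in
germline, not a homolog.  Only V and J segments are consulted (D-segment
identification is unreliable), so most of CDR-H3 can never be
germline-flagged.  Under `mode=any` a hit is flagged iff some (V, J)
segment pair jointly covers all its residues; the assigned pair is one of
the candidates, which makes `any` a strict superset of `assigned`.

The therapeutic table counts each (motif, start) at most once per chain and
divides by the number of panel chains of that class; kappa and lambda are
pooled into one `light` class because IMGT positions are comparable across
light loci and marketed panels are small (a per-locus switch exists).
Exact rational counts are stored alongside float frequencies so the 5%
threshold can be tested without floating-point ambiguity.

The surface flag computes Shrake–Rupley SASA over heavy atoms of the full
H+L complex using a deterministic golden-section spiral, so results are
bit-stable.  Relative SASA divides by the residue type's theoretical
maximum accessible area (Tien-style constants shipped as data) and is
capped at 1.0: the maxima are Gly-X-Gly tripeptide values, which an
isolated residue can exceed.  Pairing is required because an isolated
chain's interface residues would be misclassified as exposed; occlusion
monotonicity (isolated-chain SASA ≥ complex SASA per residue) is enforced
by test.  A mixed motif is `partial`; by default partial is not benign, the
conservative choice.

Statistical benchmarks use a two-sided Fisher's exact test
(probability-mass rule), Welch's unequal-variance t-test, and pairwise
chi-squared on per-sequence liability-count histograms with Bonferroni
correction over the number of pairs (bins pooled when an expected count
falls below 1).  For the oxidation benchmark a molecule counts as "with
flag" iff at least one of its annotated methionines is benign under the
combination, and only molecules with annotated methionines enter the
table — predicting no oxidation where there is no methionine would count
as a true negative without any prediction being made.

## QC filters

Applied in order, first failing rule recorded per record: chain length in
[40, 1000]; no `'!'` character; standard 20 residues only; numbering and
germline assignment present; all three CDRs non-empty; for paired input
exactly one heavy and one light chain; deduplication on the exact
variable-domain string (paired: concatenated H+L).  The `'!'` check runs
before the general residue check so both reasons remain observable.
Rejections are data (a ledger), not exceptions, and filtering is
idempotent.

## Synthetic data

The generator produces everything the pipeline consumes, with exact
ledgers:

* **Germline set** — five V subgroups (IGHV1/3/4, IGKV1, IGLV1; two alleles
  each) over IMGT 1–106 with standard gaps at 10 and 73, conserved Cys at
  23/104, and one J per locus over 115–128.  Each subgroup carries a small
  set of intrinsic CDR liabilities (e.g. IGHV3: NG at 56, DS at 62) and
  nothing else.
* **Chains/units** — V + CDR3 filler + J, with plan motifs planted at
  admissible positions.  Backgrounds are drawn from a liability-inert
  alphabet (no C, W, M, N, D, P, T — no reference motif can be assembled
  from it), and flanks are locally re-sampled until a scan of the finished
  chain reproduces exactly the ledger (inherited germline motifs plus
  plants).  Plants keep a two-residue margin from other motif spans so no
  unrepairable composite motif can straddle two protected spans.
* **Therapeutic panels** — each planned (motif, position, frequency) is
  carried by exactly `round(f·n)` chains; non-representable frequencies are
  rejected.
* **Toy structures** — CA-only chains on a coarse curve at 5.5 Å spacing
  (wide enough that burying one residue does not bury its neighbours),
  light chain parallel at 10 Å; residues planned as buried are wrapped in a
  dense dummy-atom shell at 3 Å.
* **Benchmark records** — %modification drawn from Beta distributions with
  low mean for flagged and high mean for unflagged hits (concentration 10),
  fixing the effect direction by construction.

The generator emulates IMGT gap structure, subgroup identity and
germline-inherited motifs; it does **not** model clonal structure, somatic
hypermutation or realistic CDR3 length distributions.  Passing tests
therefore demonstrate correctness of the detection/flag/accounting
machinery, not calibration against real repertoires; corpus-level survey
numbers on real data require real germline sets, a curated marketed panel
and predicted structures.

## Numerical choices

* SASA determinism: fixed golden-spiral lattice; the independent test
  oracle is a seeded Monte-Carlo integrator at 4× density, agreement
  required within 2% (2 Å² floor, the lattice quantization scale).
* Fisher p-values come from `scipy.stats.fisher_exact`; tests pin them to
  an exhaustive hypergeometric enumeration written from `math.comb`.
* Degenerate Welch input (two identical zero-variance samples) returns
  p = 1 by convention.
* Tie-break in reporting: at most one match per motif per start position
  (the Table's alternation branches are disjoint in practice).
* Reports print counts with 0 decimals, frequencies with 4, p-values in
  scientific notation, and embed a config hash for diffable provenance.

## Problem sizes

The shipped test-suite and acceptance script run on deliberately small
instances chosen to exercise every code path while staying desk-scale: a
60-unit paired synthetic corpus, 20-chain panels, 1,000 random chains for
the scanner/oracle equivalence check, 50 structure seeds for burial
recovery, and 10 random toy structures for the SASA oracle.

## Known limitations

* Numbering is consumed, not computed; inconsistencies between numbering
  tool versions propagate into liability positions.
* The default reference pins the published 13-category set; in-house
  extensions load from the documented TSV format.
* Whether the 5% therapeutic threshold should be computed over molecules
  rather than chains, or over marketed-only rather than all therapeutics,
  is not settled; the default is chains of the supplied panel,
  configurable upstream by choosing the panel.
* SASA is computed on exactly the residues provided (no side-chain
  reconstruction, hydrogens ignored); CA-only toy structures are a
  geometric caricature adequate for threshold logic, not energetics.
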