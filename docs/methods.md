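# Methods

## Disorder calling and per-protein summaries

Input is one score track per (protein, predictor): a disorder probability
in [0, 1] per residue.  A residue is called disordered when its score is
**greater than or equal to 0.5**; the boundary is inclusive by definition
of the threshold rule, and the synthetic generator therefore keeps
ordered-side scores strictly below 0.5.

Per protein we derive: the mean score; the disorder ratio `D_ratio`
(fraction of disordered calls); the IDRs (maximal runs of ≥ `min_window`
consecutive disordered residues, default 30 — long regions only, so
flexible linkers and loops of globular proteins are not counted); and the
disorder class.  The class bands form a half-open partition of [0, 1]:

| class   | band                |
|---------|---------------------|
| ORDERED | D ≤ 0.1             |
| LD      | 0.1 < D < 0.3       |
| MD      | 0.3 ≤ D < 0.5       |
| HD      | D ≥ 0.5 (the IDPs)  |

The half-open convention closes the gap between a "0.3–0.49" medium band
and the D ≥ 0.5 IDP rule: every value, including 0.49 and 0.5, belongs to
exactly one class, which a total classification needs.  "Ordered" is a
band (D ≤ 0.1), not "zero IDRs": a protein can carry one ≥ 30-residue IDR
and still be ordered if the region is a small fraction of a long sequence.

IDR coordinates are 1-based inclusive in all summaries; the on-disk
BED-like interval export is 0-based half-open, and each file header states
its dialect.

## Consensus across predictors

A residue is raw-consensus disordered when the fraction of predictors
calling it disordered is ≥ `agreement_fraction` (default 0.625, i.e. 5 of
8 — the majority-style constant of consensus disorder predictors, here
configurable because published descriptions name the approach but not the
constants).  The raw mask is smoothed by morphological closing followed by
opening with a centered structuring element of half-width `morph_radius`
(default 3), then disordered regions shorter than `min_region` (default
20) are dropped.

Boundary handling: the mask is zero-padded by twice the radius (the
protein is embedded in an infinite *ordered* background) before the
morphology and cropped afterwards.  This makes closing∘opening the exact
identity on isolated runs longer than the element — including runs that
touch the protein termini, which naive border handling either erodes or
extends.  Closing bridges gaps of up to `2·morph_radius` residues; two
planted blocks separated by more than that remain distinct.

The headline `D_ratio` and class are computed from a configurable
reference mask, default `"consensus"`; any single predictor id can be
designated instead, since real analyses alternate between a curated
reference track and individual predictors.

## Enrichment

Over-representation of a foreground set in a term map uses the upper-tail
hypergeometric probability `P(X ≥ k)` (scipy's survival function, stable
in far tails), adjusted by Benjamini–Hochberg step-up (via statsmodels;
Bonferroni available).  Only over-representation is tested.  The default
background universe is the annotated universe (proteins carrying at least
one term), the conservative common default; the whole proteome is
available by configuration.  Significance applies to the adjusted value at
α = 0.05 by default; filtering on the raw p-value is configurable because
published workflows are often ambiguous on this point.  Terms with no
background member are skipped and reported, never silently dropped.

## Network analysis

Edges are undirected and deduplicated; self-loops are retained and
contribute **one** to a node's degree (the "number of interactions"
semantics of interaction databases).  The edge reader accepts a minimal
two-column TSV with an optional multi-validated flag column and ignores
extra columns, so exported slices of wider interaction tables can be used
directly.

Degree distributions per disorder band (L/M/H; ordered proteins excluded,
matching how disorder-stratified degree analyses are reported) are
compared with two-sided Wilcoxon rank-sum tests: exact null enumeration
when both samples have ≤ 10 observations and no ties, otherwise the
normal approximation with continuity correction and midrank tie handling.
Sidedness is two-sided by design choice.  The Bonferroni multiplier is the
number of pairs actually tested (3 for three groups).  No outlier trimming
is ever applied to the statistics, and the package draws no figures, so no
display trimming exists either.

Partner proportions: for each focal category, every incident edge
contributes the partner endpoint's category once (a self-loop contributes
the node's own category once); rows are normalised to 1 where the focal
category has at least one edge, and left at zero (flagged by a zero count
row) otherwise.

## LLPS stratification

Proteins with `pLLPS > 0.64` are classified high-propensity.  The
inequality is strict by default (0.64 itself is "low") because the
defining rule is "higher than the cutoff"; published figure legends mix
≥/≤ conventions at the boundary, so an inclusive variant is configurable
and the active convention is written into the output header.  The
crosstab reports counts by LLPS class × disorder class × TF flag × stress
membership, the fraction of high-propensity proteins per stratum, and
(when a network is supplied) the partner-proportion matrix by LLPS class.

## Synthetic proteome generator

The generator's defaults are the study conditions: 2,000 proteins (the
analysed proteome of 6,721 scaled to desk size), lengths uniform in
200–800 residues, 2.5 % TFs, and a D_ratio mixture planting 40.0 %
ordered, 39.3 % LD, 13.0 % MD and 7.7 % HD — matching an IDP share of
7.7 % and ~79 % of the proteome below D = 0.3.  Mixture intervals keep a
margin inside the class bands (e.g. HD is planted in [0.52, 0.88]) so the
planted class is unambiguous under the half-open partition.

Disordered blocks are ≥ 30 residues (so truth aligns with the IDR window
definition), placed uniformly at random without overlap and separated by
at least 7 ordered residues — one more than the consensus closing can
bridge — so each planted block is recoverable as one maximal run and
noise-free generation is recovered *exactly* by the pipeline.

Score tracks: the truth profile is 0.8 inside blocks and 0.2 outside;
each residue is emitted on the truth side of the 0.5 threshold with
probability `predictor_agreement` (default 0.95) and on the wrong side
otherwise, with truncated-Gaussian jitter (sd 0.1) confined to the side.
Marginal binarised concordance with truth therefore equals the agreement
parameter exactly, which the tests verify against binomial error.

Pathways: five stress-map terms with sizes proportional to the reference
stress maps (101/110/182/138/150 members per 6,721 proteins) unless given
explicitly; members are drawn without replacement with true IDPs weighted
by the planted odds (default 5 in four pathways, 1 in the ion-homeostasis
term).  Degrees are Poisson (baseline mean 8, close to the reference
network's 2·17,771/4,126) with a +5 boost for HD TFs, realised by
configuration-style stub pairing; deduplication after pairing removes a
negligible number of duplicate pairs at these densities.  pLLPS is
`clip(0.9·D_true + 0.2 + N(0, 0.05), 0, 1)`, so the high-LLPS share rises
with disorder and a protein at the IDP boundary sits near the 0.64
cutoff.  All randomness flows from the single spec seed through one
generator instance; equal seeds give bit-identical datasets.

What the generator does **not** emulate: realistic amino-acid composition
of disordered regions (sequences are uniform over the 20 residues);
sub-30-residue disorder stretches (real proteomes have many, so the
synthetic "fraction of proteins with ≥ 1 IDR" runs higher than real
proteome-wide values); correlated predictor errors (each track errs
independently); and scale-free network topology (degrees are Poisson, so
hubs are planted by group mean, not by a heavy tail).  Passing tests
therefore validate the statistical machinery, not the biology of any real
proteome.

## Problem sizes and statistical-check conditions

The power and recovery checks run at sizes chosen for stable Monte-Carlo
behaviour: IDP-fraction recovery at n = 2,000 with a planted fraction of
0.08 (3·binomial-SE band ±1.8 points); enrichment power with a pathway of
40 members planted at odds 5 in a 1,000-protein universe with a 15 %
foreground fraction — conditions under which the analytic power of the
BH-adjusted hypergeometric test is ≈ 98 %, comfortably above the 95 %
detection requirement (at a 7.7 % foreground fraction the same
odds/member setting has only ~88 % power, which is why the check's
universe is its own design condition, stated here); degree power with
~200 TFs per disorder band and a +5 planted effect; type-I control with
200 null seeds.  The exhaustive oracle suites (hypergeometric tails for
all universes ≤ 60; rank-sum enumeration for all tie-free samples of
sizes ≤ 6; 10,000 random masks against a brute-force run scanner) are
bounded so the whole suite stays in a few minutes.

## Known limitations

- The consensus constants (0.625 / radius 3 / min region 20) are one
  sensible parameterisation of majority-consensus smoothing, not a
  reimplementation of any specific published predictor.
- BH-adjusted significance on hypergeometric p-values is conservative for
  heavily overlapping terms; no term-redundancy reduction or ontology
  propagation is performed.
- Real-data headline figures (e.g. an exact IDP count for a given
  proteome release) depend on the external database releases feeding the
  score tracks; the pipeline reports them but asserts nothing about them.
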