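# Methods

## Scope and data model

The package analyses *orthologous intron couples*: pairs of introns at
topographically corresponding positions in two species' orthologous genes,
supplied 5′→3′ on the mRNA sense strand and compared ungapped, position by
position, at the intron ends. Internally everything is DNA alphabet
(U→T on read); coordinates are 1-based and closed. The donor (initial)
hexanucleotide is the intron's first six nucleotides with variable
positions 3–6; the acceptor (terminal) hexanucleotide is the last six,
indexed left-to-right h1..h6 so h5h6 = AG, with variable positions 1–4.
The 3′ identity profile instead counts positions backwards from the
intron's last base; the two conventions meet at p = 7 − h, and that
mapping is confined to the identity module.

Couples are dropped (with a logged reason) when either member is shorter
than 12 nt (the two hexanucleotides must not overlap), carries N inside a
terminal hexanucleotide (the four-letter composition tables must sum to
100%), or — by default — is not canonical GT…AG. The reference dataset the
defaults are modelled on contained canonical introns only; how
non-canonical couples "should" be handled is therefore this package's own
decision, and the filter makes it explicit and optional
(`require_canonical`).

## Identity profiles

Identity at position p is the fraction of couples whose members carry the
same base there. Couples shorter than p at either member leave both
numerator and denominator; N in either member counts as non-identical but
stays in the denominator (conservative). Plateau means are unweighted
means over a position range; defaults 7–50 (5′ body), 7–21 and 22–50 (3′
near/far), reflecting the empirically distinct background levels near the
acceptor (polypyrimidine-tract territory) versus deeper in the intron.

Two exact cross-checks tie the modules together on any dataset: the
identity at a hexanucleotide position equals the conservation table's
actual-conservation total at that position, and the mean hexanucleotide
mismatch count equals the sum over variable positions of one minus
identity (linearity of expectation).

## The random-association conservation model

Per variable position p and base b the model compares

- random conservation = f_A(p,b) · f_B(p,b), the chance both species show
  b at p if lineages were associated at random, and
- actual conservation c(p,b), the observed both-species fraction;

their gap measures selective retention of the ancestral base. For a
wildcard motif fixing bases at a position set S, the null probability is
the product of c(p, b_p) over S — joint conservation under independence of
positions given the per-position conservation levels. The observed joint
count is tested with an exact binomial tail (scipy's `binom`; the observed
value is included in the tail, upper tail when the observed frequency
exceeds the null, lower otherwise). No normal approximation is used
anywhere; the count-scale dispersion `sqrt(n p (1-p))` is reported for
readability next to percentages, in count units.

`motif_scan` enumerates all Σ_k C(4,k)·4^k = 624 patterns per end and
reports raw one-tailed p-values, flagging at alpha (default 0.05) with no
multiple-testing correction — that is the scan the model was designed
around, where the interesting structure is the identity of the flagged
motifs rather than a family-wise guarantee. A Benjamini–Hochberg adjusted
column is emitted alongside as a clearly separate, modern extension.

Two calibration facts matter when interpreting the scan:

1. Choosing the tail by the observed direction makes the per-pattern
   procedure a pair of one-sided tests; under a true null each direction
   rejects at most alpha, so the combined flag rate can approach 2·alpha.
   The tests assert per-direction calibration.
2. When the null table is *estimated from the same sample* (the standard
   use), estimation error co-varies with the observed joint count, making
   the scan conservative — most extremely for single-position patterns,
   whose null probability equals their observed frequency by construction.
   Calibration is therefore verified against the generator's ground-truth
   conservation table, where the exact-test guarantee applies cleanly.

The species-composition test (is a base significantly more used in one
species?) is constructed as the larger count tested one-tailed against the
other species' observed proportion as the null; the construction is a
package decision (the choice of null species is not canonical) and is
isolated in `species_composition_test`.

One further wrinkle in the reference values: the published worked example
for A at donor position 3 uses 0.570 as the second species' marginal while
the published composition table prints 57.5%. The worked example's own
inputs are kept (in `WORKED_EXAMPLE_POS3_A`) for reproducing that
calculation; the reference table stores the printed 57.5.

## U1 pairing

The U1 snRNA 5′ recognition element, written ACTTAC in DNA alphabet, pairs
antiparallel with the donor region: donor position i pairs with element
position 7−i, so the perfectly complementary donor is GTAAGT. Matching is
strict Watson–Crick by default; G·U wobble (G·T in DNA space) is available
behind a flag but excluded from standard scores, because the reference
aggregate scores a G opposite the element's U position as a mismatch.
Registers −3..0 slide the element up to three nucleotides into the exon
tail, the only extension described for this interaction; ties prefer the
canonical register 0.

## Variant classification

Transcript structures are ordered, disjoint 1-based exon intervals on the
gene axis. Canonical exons with no overlapping variant exon become
exon-skipping events (consecutive runs merged into one event, since a
multi-exon skip is one phenomenon; each skipped exon's acceptor counts as
silenced). A variant exon sharing exactly one boundary with its canonical
partner is an alternative-acceptor (left boundary) or alternative-donor
(right boundary) event with a signed offset, negative upstream;
`frame_preserved` is `length_change % 3 == 0`. Intron retention,
alternative first/last exons, and exon inclusion relative to the reference
are outside the recognised catalogue and are surfaced as `unrecognized`
events — never silently dropped, never mislabeled (swapping the inputs of
a skipping pair yields `unrecognized`, not a spurious skip). The
variability summary counts unique canonical sites (a site hit by several
variants counts once) over supplied site totals.

## Synthetic data generator

Per couple: an ancestral hexanucleotide at each end is drawn from a usage
distribution (defaults: the reference dataset's printed frequent hexamers,
64.5%/36.8% of mass, remainder spread uniformly over the other canonical
hexamers — the full empirical distributions are unpublished). At each
variable position, with probability equal to the configured conservation
both species keep the ancestral base; otherwise species A keeps it and
species B is resampled uniformly over the three *other* bases. Forcing the
non-conserved lineage off the ancestral base makes realised identity equal
the conservation parameter exactly in expectation, with no
identity-by-chance correction. The intron body works the same way with
identity set by the plateau parameters (0.554 / 0.631 / 0.560); where the
5′ and 3′ 50-nt windows would overlap in a short intron the 3′
segmentation wins. Both members share one drawn length (ungapped
comparison assumes near-equal lengths); default range 120–400 nt so both
50-nt windows are always populated. Canonical GT/AG are enforced by
construction.

`correlated_motifs` entries `(pattern, w)` give matching ancestors an
extra probability w of retaining the whole hexanucleotide intact in both
species before the per-position model applies — the minimal mechanism for
whole-configuration conservation excess. Note that the *default* usage
maps are themselves position-correlated (mass concentrated on GTGAG·/
GTAAG· rows), so even without a boost the joint conservation of frequent
motifs exceeds the product of marginals; a truly null configuration uses
empty usage maps (uniform, position-independent ancestors).

`GroundTruth` records ancestors and retention masks and can compute the
exact conservation table and joint pattern probabilities implied by a
config, which is what the calibration and parameter-recovery tests
compare against. All draws flow from one `numpy` generator stream seeded
by the config, so output is byte-reproducible.

What the generator does *not* emulate: indels and alignment gaps,
substitution-rate heterogeneity and transition/transversion bias, branch
lengths, the branch point and polypyrimidine tract as structured signals,
and inter-couple dependence (shared genes). Passing tests on generated
data therefore validate the statistical machinery under its stated model,
not the biology of any real genome.

## Numerical and reporting choices

Exact binomial tails come from scipy's regularized-incomplete-beta
implementation and are verified against a brute-force `Fraction`-exact pmf
summation oracle for all k at n ≤ 50. Degenerate nulls (p0 of 0 or 1)
return 1 when the observation is the value the null forces and 0
otherwise. Internal arithmetic is never rounded; reports print fractions
to 4 dp and percentages to 2 dp with fixed float formatting so reruns are
byte-identical. Scan results sort by p-value with the pattern string as a
deterministic tie-break.

## Problem sizes used in the test suite

Simulation-backed tests use n = 5000 couples for parameter recovery
(tolerance 3·sqrt(c(1−c)/n)), 200 replicates × n = 1000 for type-I
calibration, 30 replicates × n = 216 for power against an injected
GTGAGx retention boost of 0.3 (realised actual−random excess ≈ +8
percentage points at the reference sample size), and n = 2000 for plateau
recovery — sizes chosen so sampling noise is far below the asserted
tolerances while the whole suite stays fast.

## Known limitations

- The ungapped position-by-position comparison is only meaningful for
  couples whose ends align without indels; no alignment is attempted.
- The motif scan's plug-in null (estimated conservation table) is
  conservative; ground-truth calibration is only available on synthetic
  data.
- Non-canonical splice-site classes (GC–AG, AT–AC, U12-type) are excluded
  by the canonical filter, not modelled.
- The variability summary needs externally supplied canonical site totals;
  it does not infer them from annotation.
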