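# Methods

## Scoring model

The scanner uses a position-independent composition model: the score of a
window is the sum over its residues of `log2(P_prion(a) / P_background(a))`
bits. This form was chosen over a window HMM because the phenomenon being
detected — N/Q/S/G-biased low-complexity regions — is compositional, not
positional: the score of a window is invariant under permutation of its
residues, additivity holds under concatenation, and the bit scale makes
the call threshold interpretable as a likelihood ratio (50 bits means the
window is 2⁵⁰ times better explained by the prion composition than by the
background). The model object is pluggable, so an order-aware scorer can
be substituted without touching the scanning or calling machinery.

Model parameters:

* **Prion composition** (packaged TSV, user-replaceable): N 0.30, Q 0.21,
  S 0.11, G 0.11, remaining 0.27 spread uniformly over the other 16
  residues. This is the composition observed in detected prion-like
  regions of bacterial proteins, consistent with yeast prion domains.
* **Background composition** (packaged TSV, user-replaceable): an average
  bacterial residue composition (A 8.9%, L 9.9%, N 3.9%, Q 3.9%, ...).
  Under these two models a window drawn from the prion composition scores
  about +1.1 bits per residue in expectation and a background window about
  −1.1, so the 50-bit threshold at window length 60 demands a strong,
  sustained bias (≈ 0.83 bits/residue minimum) and is essentially
  unreachable by background fluctuation (the best window of a 600-residue
  background protein sits ~8 standard deviations below the cutoff, hence
  the observed per-protein false-positive rate of 0 in 10⁵ synthetic
  proteins).
* **Pseudocount** 1e-4, added to every residue weight before
  normalisation: keeps log-ratios finite when a user model assigns zero to
  a residue. Note that reloading a written model file re-applies the
  pseudocount; at 1e-4 this perturbs probabilities by < 2e-4 per cycle.
* **Window length 60, step 1, cutoff 50 bits.** Prion-like domains are
  tens of residues long; 60 is short enough to resolve a minimal domain
  and long enough that the cutoff requires genuine compositional bias.
* **Cutoff comparison**: scores are rounded to 6 decimal places and the
  call rule is `score ≥ cutoff` by default (`strict_greater=True`
  switches to `>`). Ties at a real-valued cutoff are practically
  impossible; the rounding exists so the rule is reproducible across
  platforms rather than dependent on the last float ulp.

## Calling rule

All windows at step 1 are scored. If the maximum reaches the cutoff, the
call is the union of the run of qualifying windows that contains the
maximal window (runs merge across gaps of at most `merge_gap` residues,
default 0, i.e. only overlapping or adjacent windows merge); its score is
the best-window score. One call per protein — mirroring per-protein
counting in proteome-scale censuses — with any other qualifying runs
retained as secondary regions in a diagnostics channel, not counted.
Whether a domain-scale score should be the best-window score or some
aggregate over the region is a genuinely open choice; the best-window
convention was adopted because it makes the call threshold and the
reported score the same quantity. Coordinates are 1-based inclusive
everywhere. A protein shorter than the window is scanned as a single
window of its own length.

The positional classification of a call against a protein's Pfam
architecture labels a call `overlapping` when it overlaps any domain by
more than 10% of the call length; incursions within that tolerance do not
change the positional class, so a call that ends a few residues inside the
first domain still counts as N-terminal.

## Enrichment statistics

The enrichment factor `EF = (n_l · p_b) / (n_b · p_l)` is computed as
exact integer arithmetic followed by one division. Significance uses the
one-sided hypergeometric tail `P[X ≥ n_l]`, `X ~ Hypergeom(p_b, n_b,
p_l)` — exact, and verifiable against brute-force enumeration — with
Benjamini–Hochberg step-up adjustment (via `statsmodels`) and the strict
filters `log2 EF > 0.5`, `q < 0.1`.

Universe conventions deserve care. `p_l` counts only PrD proteins that are
annotated in the namespace under test (a protein with no GO terms cannot
contribute a hit, so leaving it in the list universe would dilute every
term). For the background, two modes are supported: `all` (every protein
in the annotation table, matching the reading of EF's denominator as "the
total number of proteins") and `annotated` (only namespace-annotated
proteins). These universes are *not* interchangeable: with `all`, the
annotated-only list is compared against a background diluted by
unannotated proteins, which inflates EF for every term by the reciprocal
of the background annotation rate and makes the hypergeometric test
anti-conservative. The recovery tests therefore use the coherent
`annotated` mode; `all` remains the default for census-style exploration
where the user controls the interpretation. Terms absent from the
background (`n_b = 0`) are skipped with a warning. No GO-graph ancestor
propagation is performed; terms are counted as given.

## Census and structure statistics

The Pfam census counts domain instances (a domain twice in one protein
counts twice) across PrD-called proteins and keeps families with count
strictly greater than 5 — the boundary is a tested contract (5 excluded,
6 included). "Multi-domain" means ≥ 2 domain instances, not ≥ 2 distinct
families, because repeated domains (e.g. tandem GTP-binding elongation
factor domains) are a real architectural signal. Domain-combination
counting uses each protein's full ordered domain-ID tuple. The functional
cluster map (IDs → named clusters such as "cell wall dynamics") is
curated data shipped as an editable YAML fixture, not an algorithm;
`cluster_rollup` conserves totals by construction, with unmapped IDs
pooled under `unclustered`.

## Reporting

Every reported percentage is `100·num/den` rounded half-away-from-zero at
an explicit per-field decimal count (1 decimal for the PrD fraction, 2 for
the annotated fraction, 0 for the domain percentages) — so every printed
ratio is exactly recomputable from the integer counts emitted next to it.
One caveat: a source that truncates rather than rounds (40.5% printed as
40%) will not be reproduced by this rule; the rule is the package's
contract, not a universal re-printer.

## Synthetic data

`generate_proteome` draws each protein residue-wise from the background
model (length uniform on 200–600 residues — bracketing typical bacterial
protein lengths and guaranteeing a planted segment always fits), then
replaces a uniformly placed segment (length uniform on 60–150) with
prion-composition residues in a Bernoulli(`prd_fraction`, default 0.003)
subset of proteins. Replacement rather than insertion keeps the length
distribution exact and the truth bookkeeping trivial. `generate_annotations`
assigns each catalogued term independently at a per-term baseline
probability (default 0.02 over 50 terms), raises planted terms to
`fold × baseline` (capped at 1 with a logged warning) on PrD-truth
proteins, gates GO annotation of PrD proteins by `annotated_fraction`
(default 0.11), and lays non-overlapping Pfam domains into equal-width
blocks per a small architecture distribution. Every draw comes from a
substream seeded `[seed, stage, protein_index]`, so outputs are pure
functions of (params, seed), independent of iteration order, and
byte-identical across runs.

What the generator does *not* emulate: real gene content, homology and
phylogenetic correlation between proteomes, genuine GO-term co-occurrence
structure, domain-length and -position distributions of real Pfam hits,
and sequence correlations within real low-complexity regions (the planted
segments are i.i.d. draws). Passing recovery tests therefore demonstrate
that the machinery detects what it models — compositional bias at the
stated contrast — not that the default models are optimal for any
particular organism.

## Recovery performance and problem sizes

With all defaults (10,000 proteins, 0.3% planted fraction), pooled over
10 seeds, the scanner's sensitivity is ≈ 0.99 with 0 false positives
(bound tested: sensitivity ≥ 0.9, false-positive rate ≤ 10⁻³ per
protein). Planted-term recovery is tested at 4,000 proteins, 8% PrD
fraction and full annotation so that planted terms realise `n_l ≥ 10`:
over 20 seeds ≈ 97% of planted terms with fold ≥ 2 are flagged and ≈ 5%
of flagged terms are unplanted (bounds: ≥ 90% and ≤ 10%). These problem
sizes keep the full suite under a minute while leaving the binomial noise
small relative to the tested margins.

## Degenerate inputs and tie-breaks

* Empty proteome, empty call set, zero denominator, out-of-range
  p-values: argument errors.
* All-domainless call set: multi-domain percentage reported as 0 with a
  warning rather than NaN.
* A call set with no calls scores precision 0 with a warning.
* Census and combination tables break count ties by ID for deterministic
  output ordering.
* Duplicate FASTA accessions are deduplicated by accession (first
  occurrence wins); duplicate annotation rows merge by union.

## Known limitations

* The scorer is composition-only; it cannot distinguish two regions of
  identical composition but different residue order, and its absolute
  scores are model-dependent (they are not comparable across different
  background models).
* Enrichment treats annotation terms as independent flat labels; the
  hierarchical structure of GO is ignored, so parent/child terms can both
  appear as (non-independent) hits.
* The pathogen flag is user-supplied metadata; the pipeline performs no
  taxonomic inference.
* Figure-level enrichment values from database-snapshot-dependent runs
  (e.g. fold enrichments of specific terms against a particular GOA
  release) are not reproducible from synthetic data and are out of scope.
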