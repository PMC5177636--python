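# Methods

## Window signature statistic

Each fragment is cut into windows of `window_length` (default 300 bp)
every `step` (default 100 bp) from the first base; a trailing stretch
shorter than one window is dropped. Two strand-handling modes exist:

- `per_window_rc` (default): each window is counted together with its
  own reverse complement as two separate strands (no k-mer spans the
  junction). This makes the signature strand-symmetric — the z-vector
  of a window equals that of its reverse complement up to the
  reverse-complement permutation of components, so a window and its
  mirror correlate at exactly 1.
- `whole_sequence_rc`: the reverse complement of the whole sequence is
  appended before windowing and each window is counted single-strand.
  This reproduces the literal extend-then-cut recipe of older scripts;
  every window reappears in mirrored form and windows can span the
  junction. Region coordinates from the mirrored half are mapped back
  onto the original sequence.

Within a window, observed tetranucleotide counts are compared with the
maximal-order Markov expectation E = N(n₁n₂n₃)·N(n₂n₃n₄)/N(n₂n₃) and
variance var = E·(N(n₂n₃)−N(n₁n₂n₃))·(N(n₂n₃)−N(n₂n₃n₄))/N(n₂n₃)²,
giving Z = (N−E)/√var per tetranucleotide. This expectation is exactly
what a 2nd-order Markov process predicts, so Z carries the genuine
higher-order structure of the sequence plus sampling noise; windows
from the same genome share the former, which is what the pairwise
Pearson correlation of z-vectors detects.

Numerical conventions, chosen to keep every window's vector finite and
256 components long:

- E = 0 whenever the core dinucleotide count N(n₂n₃) = 0; Z = 0
  whenever var = 0 or E = 0.
- k-mers containing ambiguous bases (N etc.) are skipped and the
  count bookkeeping adjusted.
- A zero-variance z-vector (degenerate window, e.g. a homopolymer)
  correlates as 0 with a warning instead of propagating NaN.
- Matrix diagonal is set to 1 exactly; the unit-diagonal tolerance
  used in validation is 1e-9.
- `mean_r`/`sd_r` summarise the strict upper triangle; SD uses the
  sample (n−1) convention. The published summary values do not state
  either convention; this is the package's fixed choice.

## Region calling

Each unmasked window is scored by its mean correlation against all
other unmasked windows (masked windows — typically rRNA, whose
composition is universally distinct from the host genome — take no
part on either side). The caller then:

1. smooths scores with a moving average of half-width 2 windows,
2. places the flagging threshold automatically at the midpoint of a
   two-means split of the smoothed scores (an explicit `threshold`
   overrides this), and declines to call anything when the two levels
   are separated by less than `min_separation` (default 0.07) — the
   guard that keeps homogeneous fragments call-free,
3. flags windows below threshold and joins flagged windows separated
   by at most `max_gap` (default 8) unflagged ones; candidate regions
   need at least `min_run` (default 8) flagged windows,
4. sharpens each region's boundaries by an outside/inside/outside
   piecewise-constant least-squares changepoint fit on the unsmoothed
   scores (searched within ±15 windows of the coarse edges).

The smoothing, gap-joining and changepoint refinement exist because
single-window scores are noisy and serially correlated (adjacent
windows share two-thirds of their sequence): raw threshold crossings
fragment a real implant into several runs and bias its edges inward by
one to three windows. On the default synthetic conditions the refined
boundaries recover a 10 kb implant's edges within ±1 window in ≈95% of
seeded runs with no false calls on homogeneous fragments.

Defaults favour multi-kilobase regions (min_run 8 ≈ 1 kb of unique
sequence); single anomalous windows are deliberately not callable.

## In-silico screening

PCR is modelled as IUPAC-degeneracy-aware site finding: the forward
primer (default 27F, `AGAGTTTGATCCTGGCTCAG`) matched on either strand
with at most `max_mismatch` (default 2) mismatches and none in the
three 3′-terminal bases, the reverse primer (default 1492R,
`GGTTACCTTGTTACGACTT`) matched as its reverse complement downstream on
the same template, and the product length constrained to 1,200–1,700 bp
around the canonical ~1.5 kb product. No thermodynamics: the screen
only needs presence and approximate size.

Digestion places a cut after `cut_offset` bases of every occurrence of
the recognition site (*Hha*I default GCGC, offset 3), counting
overlapping occurrences individually; enzymes blocked by overlapping
sites are out of scope. Fragment profiles are compared by optimal
one-to-one length assignment (scipy's linear sum assignment) where a
pair is admissible within a fractional tolerance (default 5% of the
larger fragment) — a proxy for two lanes looking identical on a 1%
agarose gel, and symmetric in query and control by construction. A
clone is **positive** when some amplicon's profile differs from the
host control (candidate insert-borne 16S), **negative** when every
amplicon matches, **no_amplicon** otherwise.

## Coding-density statistics

Coding percentage merges overlapping CDS intervals before summing, so
each base counts once; rRNA is never counted as coding. The cross-
clone association between coding % and mean internal correlation is the
Pearson coefficient with the standard t-transform two-sided p-value
(t = r√(n−2)/√(1−r²), df = n−2); at r = 0.895, n = 5 this yields
p ≈ 0.040, matching the printed pair to its precision, which is why
this test convention was adopted. A permutation test agrees with the
t-based p within Monte-Carlo error on synthetic summaries.

## Synthetic data generator

The generator realises the structure the scanner assumes: a host
backbone sampled from a random 3rd-order Markov model, optionally with
one implanted segment from a different model and one rRNA-like block
copied from a packaged, deterministically generated 16S-like reference
(synthetic, not a real gene; it carries exact 27F/1492R sites and
*Hha*I sites at known offsets so digest profiles are reproducible).

`make_model(gc_target, sharpness, seed)` draws per-context transition
rows as softmax(log base + sharpness·noise) and calibrates a scalar
G/C-logit tilt against the exact stationary distribution of the
induced 64-state context chain until the stationary GC is within 0.1
points of target. `sharpness` controls how much transition rows differ
across trinucleotide contexts: 0 is the i.i.d. limit (no signature at
all); larger values create the genuine 3rd-order structure that the
window statistic detects, at the cost of inflating the pooled window
z-score spread beyond the pure-sampling value of ~1.

Default study conditions: host 48% GC with sharpness 0.7; implant 60%
GC with sharpness 0.35, 10 kb in a 30 kb fragment. Host sharpness 0.7
is near the upper end of the range for which pooled window z-scores
stay within the calibrated band (SD ≈ 1.26 at window 300); the implant
is deliberately less self-coherent, reflecting that exogenous DNA is
typically compositionally heterogeneous rather than one clean second
genome, which is also what makes its windows correlate poorly with
everything including each other. Under these conditions a homogeneous
fragment has mean pairwise r ≈ 0.33 and an implanted one ≈ 0.17; the
stable/unstable contrast is qualitatively preserved, though the
absolute levels sit below those of real genomic DNA, whose signature
coherence (codon usage, repeats, operon structure) exceeds what a
3rd-order chain constrained by the z-calibration band can produce.

Fake ORF annotation covers a requested fraction of each region
(host/implant separately) with non-overlapping intervals of uniform
length 300–2,000 bp; ORF placement hits the requested coverage within
±2 points on multi-kilobase regions. Every generator output is a pure
function of its arguments including the seed.

What the generator does *not* emulate: real codon structure, repeats,
mobile elements, assembly artefacts, sequencing error, or multiple
implants per fragment. Passing tests therefore demonstrate that the
statistic and caller behave correctly on fragments with the assumed
two-composition structure, not that the default thresholds are optimal
for any particular real genome.

## Problem sizes

The test suite and the acceptance script run the power/specificity
study at 100 seeds × two 30 kb fragments per seed (one homogeneous,
one implanted), the contrast study at 5 seeds × (46 kb + 30 kb), the
distributional-fidelity check at 400 kb, and oracle comparisons on 100
random 300-mers; the whole suite completes in well under a minute on a
single core.

## Known limitations

- The published five-clone reproduction requires a one-time download
  of the GenBank records (`scripts/fetch_accessions.py`); the package
  does not redistribute the sequences, and the corresponding test
  fails with instructions until they are fetched.
- The exact windowing convention behind the published mean ± SD values
  (diagonal handling, mirrored duplicate windows of the literal
  extend-then-cut recipe, rRNA inclusion) is not stated anywhere; both
  strand-handling modes are provided and reported side by side.
- Amplicon search is exhaustive over primer-site pairs; highly
  repetitive templates could yield many overlapping candidates.
- Gel comparison by fractional length tolerance ignores co-migration
  of similar fragments on real gels beyond the tolerance rule.
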