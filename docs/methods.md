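# Methods

`stemscan` re-implements, as a reusable library and CLI, the computational
pipeline used to localise a translationally inhibitory stem-loop element in
the 5' untranslated region of human TGF-beta1 mRNA, and generalises it to
arbitrary mRNA UTR sequences.  This note records the models, parameters and
design choices behind each stage, and what the synthetic benchmarks do and
do not demonstrate.

## Insert reconstruction

The proximal +1..+167 fragment of the TGF-beta1 5'UTR (+1 = first residue
of the 5'UTR in the NM_000660 reference frame) and five adenine-substitution
mutants were cloned from pairs of ~108-nt overlapping DNA oligonucleotides.
`stemscan.tgfb1` reconstructs all six inserts purely from those printed
oligo sequences (shipped as a packaged FASTA fixture):

1. each pair anneals over its longest exact complementary 3' overlap
   (32 nt for every construct; minimum accepted is 8 nt, no mismatches);
2. primer extension is simulated by appending the reverse complement of the
   antisense oligo's non-overlapping 5' portion to the sense oligo;
3. restriction-site adapters are trimmed: the leading `cc`+HindIII clamp
   (`ccaagctt`, 8 nt), and at the 3' end the maximal suffix of the form
   `c..catg..g` containing the NcoI site.  The NcoI site supplies the
   initiator AUG of the downstream reporter, so that whole run is vector
   context; trimming it yields exactly 167 residues, consistent with the
   constructs' "+1 to +167" naming.

The endogenous insert is not printed anywhere verbatim; it is spliced from
the pGL3-50/56A sense oligo (endogenous outside +50..+56) with +50..+56
restored from the pGL3-92/105A sense oligo (endogenous through +91).
Internal consistency is verified programmatically: every assembled mutant
equals the corresponding A-substitution of the endogenous insert, and every
sense oligo agrees with the assembly wherever it covers endogenous
positions.  One printed-table nuance is handled explicitly: the pGL3-92/98A
sense oligo carries an eight-adenine run spanning +92..+99 although the
construct name claims seven positions; +99 is endogenously adenine, so the
assembly is still exactly the 92..98 substitution (flagged in the module
documentation rather than silently assumed).

Checks on the reconstruction: length 167; the 80-nt window +59..+138 counts
exactly 36 G, 36 C, 4 A, 4 U (G/C fraction 0.90); the first 21 residues
match the independent PCR amplification primer.

## Folding

Two interchangeable backends produce the same result type (MFE structure
and energy, ensemble free energy `-RT ln Z`, base-pair probability matrix):

* **thermodynamic** - an adapter over ViennaRNA.  The default
  nearest-neighbour table is **Turner 1999**, selected deliberately: the
  stem-loop analysis this package reproduces was established with a
  folding engine of that parameter era, and some of its structural
  conclusions are parameterisation-sensitive at the margin.  Concretely,
  under Turner 2004 the 92/105A ablation mutant retains a residual
  four-pair helix (+78..+81 with +86..+89) at probability ~0.74, whereas
  under Turner 1999 no pair inside +77..+105 exceeds 0.5 - the published
  observation.  The mutant free-energy increases are likewise essentially
  exact under Turner 1999 (+9.86 and +12.71 kcal/mol for the 99/105A and
  92/98A inserts) and drift by ~1 kcal/mol under Turner 2004.
  `FoldConfig(parameter_set="turner2004")` selects the modern table.
* **reference** - bespoke Zuker-style MFE and McCaskill partition-function
  dynamic programs over a simplified nearest-neighbour model: allowed
  pairs AU/UA/GC/CG/GU/UG; stack energy = minus the mean strength of its
  two pairs (GC 3.3, AU 2.1, GU 1.4 kcal/mol); constant penalties for
  hairpin (+5), interior/bulge (+3, at most 30 unpaired residues) and
  multibranch (+4) loops; minimum hairpin loop 3; lonely pairs permitted;
  unpaired residues free.  The model is deliberately simple so that every
  quantity (MFE, Z, every base-pair probability) is verified against
  exhaustive enumeration of all nested structures at n <= 12, to 1e-9
  relative tolerance.  Base-pair probabilities come from a full outside
  pass.  This backend owns the algorithmics; it is pure Python and meant
  for short sequences (tests, toy hairpins), not production scans.

Temperature is 37 C by default; RT = 0.0019872 kcal/(mol K) x T(K).
Sequences too short to form any pair return the open chain at 0.0 kcal/mol
(a result, not an error).  The "centroid" used throughout is the set of
individual pairs with probability > 0.5; thresholds below 0.5 are rejected
because two pairs sharing a residue could then both qualify.  Pairing
profiles report, per fully contained window, both the percentage of bases
in some individual pair with p > 0.5 and the percentage whose *total*
pairing probability exceeds 0.5; the second reading resolves an ambiguity
in the original figure legend ("sum of probabilities over all pairings
> 0.5") in the only way that yields a percentage commensurate with the
first series.

## Shuffled nulls

The null model conserves dinucleotide counts exactly (stacking, and hence
folding energy, is a nearest-neighbour property; eukaryotic sequence has
strong dinucleotide bias).  Shuffles are uniform draws over all
arrangements with the source's dinucleotide multiset, via the
Altschul-Erickson Eulerian-walk construction: a uniformly chosen last-edge
arborescence (rejection sampling) plus uniformly permuted remaining
out-edges, which by the BEST theorem enumerates each Eulerian path once.
Uniformity is smoke-tested against the fully enumerated arrangement set of
a short sequence (20,000 draws within five standard errors of uniform).
Duplicate members of a null set are counted and reported, never resampled -
resampling would bias the null.  For windows of >= 30 nt of the 167-mer,
100-member sets are empirically duplicate-free.

Randomness derives from one master seed through `SeedSequence` entropy
mixing keyed by (window size, window start, member index), making scans
bitwise reproducible and order-independent.

## Window scans and segment scores

Windows of 30..100 nt (step 2) slide in 1-nt steps (only fully contained
windows are scanned); each window is folded once for both energy kinds, and
one null set of 100 scrambles per window is shared between the MFE and
ensemble scores.  The segment score is `S = (E - mean)/sd` with the sample
(n-1) standard deviation; degenerate nulls (sd = 0, e.g. homopolymeric
windows) score 0 with an explicit flag rather than an infinity.  The
reported window centre is `start + floor((size-1)/2)` (left-of-middle for
even sizes) - the analysis is insensitive to any fixed convention.
Energy-per-nucleotide profiles divide the window's ensemble free energy by
its size; the null profile is the per-window mean of the same quantity over
the scrambles.  Whole-sequence calibration scans each of N full-length
scrambles with the same machinery and records each scan's minimum segment
score, placing the native extreme inside an empirical null distribution.

On the endogenous 167-mer the 50-nt-window energy-per-nucleotide minimum
falls at centre +96, inside the +77..+106 element.

## Mutant comparison

Mutants are compared on the insert itself (the sequences actually folded),
never a longer context.  `ddG` is defined on ensemble free energies
(mutant minus reference; MFE deltas are secondary columns), the mutated
region counts as unpaired when no centroid pair touches it, and gained
pairs are clustered into maximal helices (pairs (i,j) and (i+1,j-1) are
stacked neighbours) to surface alternative structures - e.g. the 92/98A
insert gains a helix joining the +70..+74 and +102..+106 neighbourhoods.

## Conservation

Percent similarity is `100 x matches / alignment length` (gap columns in
the denominator) from an optimal global alignment with match 1, mismatch 0,
gap open -3, gap extend -1 (Biopython `PairwiseAligner`).  The interactive
k-tuple heuristic used in the original desktop analysis is proprietary and
is not reproduced; an optimal global alignment is the reproducible
surrogate, so small deviations from historically printed percentages are
expected.  Orthologous copies of an element are located by aligning full
sequences and projecting the element interval through the alignment.
Accession sequences are never fetched: users supply downloaded FASTA files
(the test suite skips accession-dependent checks when none are present).

## Synthetic benchmarks

The generator samples backgrounds i.i.d. from mononucleotide frequencies or
as a first-order Markov chain matched to a dinucleotide table (the same
statistic the shuffler preserves), and plants perfect hairpins with chosen
stem length, loop length, position and stem G/C fraction; stem pairs take
random orientation so arms are not homopolymeric (which would permit
register-slipped recoveries).  Truth annotations (exact pair set, interval,
spec, seed) ride along as JSON.

Benchmarks used in the tests, with their measured operating points:

* a 12-bp planted hairpin in 200-mer backgrounds matched to the insert's
  dinucleotide composition is localised by the 50-nt-window profile minimum
  to within +/-5 nt of the planted interval in 48/50 seeded replicates
  (pinned as a regression value);
* recovery of weak A/U-only stems in G/C-containing backgrounds increases
  with stem length (6 -> 9 -> 12 bp) under the reference model.

These synthetic backgrounds are compositionally realistic but lack real
UTR features - repeats, conserved motifs, G-quadruplex-prone runs, local
composition gradients - so passing them demonstrates correct localisation
of thermodynamically planted signal, not discovery performance on real
transcripts.

## Problem sizes and numerical choices

The default test suite folds at most a few thousand 30-50-nt windows and
enumerates structures only for n <= 12 (a few thousand structures per
sequence), which keeps it comfortably interactive; genome-scale scans
should use the thermodynamic backend, whose cost is ~3 ms per 50-nt window
including the partition function.  Reference-backend partition functions
are computed in unscaled double precision, which is safe for n up to ~100
under the simplified model's energy range.  Floating-point comparisons in
the oracle tests use 1e-9 relative tolerance; TSV artefacts round floats to
six significant digits.

## Known limitations

* Pseudoknots and G-quadruplexes are out of scope (the latter was excluded
  experimentally for this element in the original study).
* The simplified reference model has no temperature-dependent entropy
  terms, so its ensemble does not "melt" with temperature the way the
  Turner parameterisation does; temperature-trend tests use the
  thermodynamic backend.
* Whole-UTR quantities (segment scores of the complete 5'UTR, full-UTR
  pair probabilities, cross-species similarity) require user-supplied
  accession FASTAs; the package never downloads sequences.
* Duplicate-freedom of null sets is probabilistic; for very short or
  low-complexity windows duplicates are expected and are reported rather
  than resampled.
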