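# Methods

This note documents the models and procedures implemented in `ismite`, the
parameters that matter, the numerical choices, what the synthetic data do
and do not emulate, and known limitations.

## Inverted-repeat detection

An IR pair is two equal-length arms on one sequence whose right arm is the
reverse complement of the left at all but a bounded number of positions.
Pairing lives on the anti-diagonals of the base-pair matrix (`x` pairs with
`c − x`), so the scanner walks each diagonal once. A window is **valid**
when (i) its terminal base pairs match (arms never start or end on a
mismatch; an N counts as a mismatch), (ii) internal mismatches ≤
`max_mismatch`, (iii) arm length ∈ `[min_arm, max_arm]`, (iv) the spacer is
non-negative and ≤ `max_gap`. The scanner reports every valid window that
is **maximal**, i.e. not properly contained in another valid window on the
same diagonal. This contract is deliberately simple enough to enumerate by
brute force; the test-suite and the acceptance script verify exact set
equality against such an enumerator on random sequences across parameter
settings.

Defaults (`min_arm=10, max_arm=50, max_gap=2000, max_mismatch=2`) are the
standard permissive IS-search settings. They are permissive by design and
admit large numbers of chance pairs (about 0.4 per base on random
sequence), which the downstream filters must remove; see below. The kernel
is O(genome × (max_gap/2 + max_arm)) and handles a 5 Mb genome in about a
minute on one core.

### From IR pairs to element candidates

A candidate is the sequence delimited by a pair, arms included (IS
convention: the IRs are terminal parts of the element). Three screens turn
the chance-pair flood into element calls:

1. **Copy number** (the doubleton rule): a candidate is kept iff it occurs
   at least twice in the genome at ≥ 90% identity over its full length.
   Occurrences are found by anchoring the candidate's 13-mers in a
   position index and verifying each putative locus with a banded
   edit-distance alignment (edlib); an occurrence must also match within
   20% over both 20 bp terminal windows, because copies of an IR-delimited
   element share their termini — this is what keeps arm pairs offset into
   an element's flank from counting their parent element's copies.
2. **Repeat-boundary ("fragment") screen**: a true element ends where its
   repeat ends. If two or more copies agree across a candidate boundary —
   near-identical 30 bp flanks on either side, or exact agreement ≥ 2 bp
   immediately beyond both ends — the candidate sits strictly inside a
   longer repeated unit (a chance arm pair within an element) and is
   dropped.
3. **Per-locus redundancy collapse**: among overlapping surviving
   candidates the one with the most genomic occurrences wins, ties going
   to the least diverged and then the longest; jittered and junk-extended
   variants of the same element lose to the flush span.

A consequence of screen 2 is that nested elements are only discovered from
their non-nested copies by this path; the partner-linking stage reconstructs
nested arrangements explicitly.

## Repeat-family discovery

Seeding uses canonical l-mers (l = 9 by default; an l-mer and its reverse
complement are one seed, so plus- and minus-strand copies share seeds);
seeds are visited by descending occurrence count. Occurrences overlapping
within l bases are collapsed (a near-palindromic word otherwise hits the
same locus twice, once per strand). From the aligned occurrences a
consensus grows outward one column at a time: the majority base (ties
lexicographic) is appended; each copy scores +1 when it agrees and −2 when
it does not, and retires when its cumulative flank score falls 10 below its
own maximum; a flank stops when fewer than `min_copies` (default 3) copies
remain. Each flank is then trimmed back to the extension that maximised the
*summed* agreement score — past the true repeat boundary every copy turns
random and the total declines, so the argmax sits at the boundary. Copies
must cover ≥ 80% of the trimmed consensus at ≥ 70% identity (fragmentary
copies betray mixed-orientation chimeras seeded on palindromic words, which
are rejected). Accepted families mask their copy intervals, so each genome
position supports at most one family, and seeds with entropy < 1 bit/base
are skipped. Everything is deterministic: ties break lexicographically then
positionally.

## Clustering

Greedy centroid clustering, longest-first (ties by id): a sequence joins
the first centroid it matches at ≥ the identity threshold (0.9 by default,
the historical default of the greedy clusterers used for this task), else
founds a cluster. Identity is matches / alignment-columns of one optimal
global alignment under +1/−1/−1 scoring; among equal-score alignments the
one maximising matches and then minimising columns is used, which makes the
quantity well-defined and oracle-checkable. Nucleotide identity is
strand-insensitive (the better of forward and reverse complement), since
element copies occur in both orientations.

## Local alignment and statistics

Both search modes (nucleotide/nucleotide and six-frame-translated/protein)
locate candidate regions by exact word seeds (word 11 nt, 4 aa), then score
each region with a full affine-gap Smith–Waterman (nt: +1/−2, gaps −5/−2;
tx: BLOSUM62, gaps −11/−1). Because the reported alignment is the DP
optimum of its window, every hit's score equals a full local DP restricted
to the reported spans — an invariant the tests assert against an
independent DP. Merged seed windows may contain several element copies; the
engine recurses into the target flanks outside each alignment so all copies
are reported. Hits contained in a better hit are pruned.

E-values follow Karlin–Altschul, `E = K·m·n·e^(−λS)`. λ is the positive
root of `Σ pᵢpⱼ e^(λ sᵢⱼ) = 1` at uniform residue frequencies (≈ 1.33 for
+1/−2), reduced by the documented empirical factor 0.9 for gapped scoring.
K is a fixed per-mode constant (nt 0.62, tx 0.04) of the usual order of
magnitude for these schemes; the pipelines depend on threshold semantics
(E ≤ 1e-5 for copy expansion and validation, E ≤ 1e-1 for the permissive
terminal-word search), not on tool-exact statistics. The empirical null —
a 1 kb random query against an independent 100 kb random genome — yields no
hits at E ≤ 1e-5 in ≥ 99 of 100 seeded trials. For 23 bp terminal words,
gapped statistics are meaningless; the E ≤ 1e-1 step is implemented as
ungapped matching with up to 3 mismatches.

## Profile HMMs

Architecture: match/insert/delete per consensus column. Columns with < 50%
gap characters become match states (exactly half gaps → insert). Emissions
are column counts plus one pseudocount-weight of the background (uniform
1/20); transitions come from the observed state paths with Laplace
smoothing. Scoring is local log₂-odds against the background with uniform
entry (1/K) into and exit (1/K) weight out of any match state; residues
outside the envelope score zero; insert states use their stored emission
distributions. Viterbi and forward are exact — verified to 1e-9 bits
against exhaustive path enumeration on small models — and run as numba
kernels, so calibration and search scale to thousands of peptides.

Calibration scores `n_random` (default 5000) i.i.d. background peptides
(lengths ~ Normal(350, 120), floored at 30) and fits a Gumbel by maximum
likelihood: `P(S > s) = 1 − exp(−exp(−λ(s − μ)))`; the fit recovers known
(μ, λ) within 5% at n = 10,000. E-values multiply the tail by the number of
frame-peptides scored per profile. Hits duplicated by window overlap are
collapsed by genome coordinate (same profile, same strand sense, ≥ 50%
overlap); hits of different profiles on one locus are all kept, since
overlapping transposase families are informative for annotation.

Serialization is a versioned plain-text format (12 significant digits,
lossless round trip; rows are re-normalised on read before validation).

## Pipelines

The 500 bp size split sends centroids > 500 bp to the IS branch and ≤ 500 bp
(boundary included, a documented convention) to the MITE branch. IS
consensus sequences are expanded to all related copies at E ≤ 1e-5,
truncated copies (< 90% of consensus length) flagged, overlapping
same-strand hits merged. MITE candidates contribute their terminal 23 bp
words; co-occurrences of a 5′ and a 3′ word in proper orientation spanning
< 3 kb form partner candidates; candidates occurring < 2 times are dropped;
nested arrangements are separated by excising contained intervals
(recursively, so A⊃B⊃C yields three reconstructions and A's excises B∪C);
surviving candidates are validated by translated search against the
transposase library, and a validated partner longer than the MITE becomes
an IS call linked from the MITE. MITEs without a validated partner are
reported as `MITE_like_orphan`; a "MITE" whose own body encodes a
transposase over > 50% of its length is reclassified `IS_like`. DRs are
annotated as the longest flank word (≤ 15 nt) duplicated identically on
both sides of ≥ 2 copies; terminal IRs of a call are re-detected on its
consensus. Family labels come from the best transposase-library hit (the
text after the last `|` of the library id). An optional decoy library
screens calls whose best decoy hit is stronger than their best transposase
hit (the false-positive screen: group-II introns, prophage integrases,
rRNA and the like).

## Synthetic data

Elements are `[IR arm] – core (optionally containing a transposase ORF
back-translated with uniform codon choice) – [reverse-complement arm]`,
inserted at uniform random non-overlapping sites with the target-site word
duplicated as DRs; MITEs are internal deletions of their partner IS
retaining both termini; nested copies are inserted inside a host copy;
per-copy substitutions are applied after the fact. A family declared
IR-less is *guaranteed* IR-less: random termini form a chance
quasi-palindrome (≥ 10 bp arms at ≤ 2 mismatches) surprisingly often, so
the generator resamples termini until the declared structure holds — this
matters because the IR-path-blindness property is about element structure,
not about luck with random ends.

The generator does **not** model sequencing error, chimeric reads,
compositional bias, real IS family diversity, or transposase domain
structure; passing tests demonstrate algorithmic correctness and the
qualitative behaviour of the workflows, not field performance on real
genomes.

Benchmark conditions (module `benchmarks`): the de novo scenario is a
300 kb genome with four IS families — with and without IRs, exact and with
5% per-copy divergence, 3–8 copies — and two MITE families partnered to two
of the ISs; negative controls are 50 kb column-shuffles of that genome. The
read-length scenario implants twelve copies of an IS whose transposase is a
~50%-identity relative of the profile's training family — the
distant-family regime in which read length governs detection (at low
divergence even 33-residue windows of a sharp profile score far above the
E ≤ 1e-5 threshold and read length has no effect); the genome is tiled into
1000/250/100 bp reads and per-copy recall is computed against the implant
truth. Sizes were chosen to keep single-core desk runtimes; they are stated
here as the package's reference conditions.

## Known limitations

* The IR scanner reports all maximal windows; on low-complexity sequence
  (e.g. AT repeats) this can be quadratic in the repeat length. Seeds and
  candidates of entropy < 1 bit/base are skipped in the repeat path but not
  in the IR path.
* Copy-number counting treats a quasi-palindromic locus as one occurrence
  per strand only when loci overlap; exactly self-reverse-complementary
  candidates are counted once.
* Families whose copies diverge by ≈ 10% sit at the 0.9 clustering
  threshold and may split into several clusters, yielding duplicate calls
  of one family (each still matching the truth locus).
* K in the Karlin–Altschul formula is a per-mode constant, not computed
  from the scoring scheme; absolute E-values are approximate, thresholds
  are conservative.
* The HMM pipeline's peptide-input path assumes one record per ORF and
  skips segmentation.
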