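# Methods

This note records the models, conventions and numerical choices behind
`afgpkit`, in the order data flows through the pipeline.

## Sequence model and coordinates

A `GeneRecord` holds one gene-scale sequence (5′ flank + CDS + 3′ flank)
with 0-based half-open CDS offsets. All arithmetic is done in these
internal coordinates; emitted GFF3 is converted to 1-based inclusive at
write time. Input is uppercased and restricted to A/C/G/T/N — the repeat
scanner is codon-exact, so ambiguity codes other than N are rejected
rather than silently tolerated. Minus-strand records are flipped to coding
orientation at load time (the original strand is retained for output), so
every downstream stage can assume a coding-strand CDS.

## Repeat-tract detection

The AFGP coding region is an imperfect tandem repeat of a 9-nt unit
encoding [Thr/Arg/Lys]-[Ala/Pro]-Ala. A unit is classified from its
translated residues: Thr-led units (TAA, TPA) are the glycosylated repeats
proper, Arg/Lys-led units (RAA, KAA) are spacers, anything else is OTHER.
Arg/Lys with Pro at position 2 does not occur in the family and maps to
OTHER.

`find_repeat_region` tiles the CDS into 9-nt units at every nucleotide
offset 0–8 (frame × phase), scores every contiguous run of units by its
number of classifiable units, and returns the best run subject to:

- at least `min_units` units (default **4**, the smallest mature isoform);
- OTHER fraction ≤ `max_other_frac` (default **0.1**);
- first and last units classifiable (leading/trailing OTHER trimmed).

Ties are broken by smallest offset, then leftmost start, then shortest
run, making the result deterministic and independent of dictionary or
input order. Scanning all nine phases (not just the three codon frames of
the annotated CDS) is deliberate: frameshifted pseudogenes carry their
tract out of register with the annotated reading frame and must still be
found. The 10% impurity default is a design choice, not a measured value —
the family's repeats are described only qualitatively as "imperfect". For
heavily mutated sequence the tolerance should be matched to the expected
corruption: with substitution load λ per site, the probability a pristine
ACA-GCA-GCA unit has left the classifiable grid is ≈ 1 − exp(−9λ·0.58)
(about 58% of the 27 possible single-base changes, weighted by a 2:1
transition bias, break the unit), and `max_other_frac` should sit above
that expectation. At λ = 0.1 (e.g. 10⁻³/site/generation over 100
generations) this gives ≈ 0.41, so analyses of such data use a tolerance
of 0.5.

`find_all_repeat_regions` applies the same search greedily to the
remaining flanks, yielding every non-overlapping qualifying run in CDS
order. Gene-level repeat totals use this set, because a long insertion
genuinely splits a tract into two runs that both belong to the gene.

## Gene vs. pseudogene classification

A gene is called functional when an uninterrupted reading frame runs from
a start codon through the repeat tract to a terminal stop: ATG at the CDS
start, a non-repetitive 5′ coding segment of at least `min_five_prime_nt`
(default **30 nt**), tract start in frame 0, CDS length divisible by 3, no
internal stop, terminal stop present. Failures map to the three defect
classes observed in real loci, checked in this order:

1. **five_prime_truncated** — no start codon or 5′ segment shorter than
   the minimum;
2. **coding_insertion** — two repeat runs separated by at least
   `insertion_threshold_nt` (default **500 nt**; the one observed case is
   a 6.5 kbp insertion, and any large interrupting tract qualifies);
3. **frameshift_indel** — everything else that breaks the frame or
   truncates translation.

The order matters: a long insertion almost always also introduces
premature stops, and the insertion is the causal defect. A CDS with no
repeat tract at all is reported as non-AFGP, not as an error.

## Cleavage sites and digestion

Sites are read from the framed unit sequence: every KAA unit is a
single-Lys site; an RAA unit whose successor begins with Arg forms the
4-residue Arg-Ala-Ala-Arg motif, otherwise it is a single-Arg site.
Overlapping RAAR motifs resolve leftmost-first. Digestion assumes
exhaustive cleavage: products are the maximal unit runs strictly between
linker spans, with linker residues excised. For RAAR the successor unit's
leading Arg completes the motif and its residual Ala-Ala dipeptide is
excised with the linker rather than left on a product — the alternative
(retaining it on the downstream product) cannot be distinguished from the
published isoform arithmetic, which is only consistent when products count
Thr-led units exclusively. Unit conservation (product units + linker units
= region units) is asserted on every digestion call. Products are reported
whenever they contain at least one Thr-led unit; fragments below four
repeats are binned `sub_AFGP` rather than dropped, so filtering remains a
view, not data loss. A retention mode (`min_repeats=0`) keeps even
Thr-free fragments for accounting.

## Mass model and size bins

Masses are average (not monoisotopic) masses in daltons: the sum of
standard average residue masses, one water (18.02 Da), and one dehydrated
galactosyl-N-acetylgalactosamine disaccharide (365.33 Da) per Thr. The
repeats only use Thr/Ala/Pro/Arg/Lys, but imperfect units can carry any
standard residue, so the model holds the full 20-residue table; unknown
symbols raise. The model omits the 2–4 characteristic C-terminal residues
of real isoforms (their composition is not specified per isoform), which
is why predicted masses run a few percent below published rounded values —
comparisons against "~" values use a ±10% band.

Size bins follow the historical AFGP 1–8 ladder: four repeats = AFGP8,
five = AFGP7, fewer than four = sub_AFGP; larger products are binned by
mass, with the AFGP6 group below 9200 Da and the AFGP1–5 group at or above
it (9200 Da is the midpoint of the 7.9–10.5 kDa gap between the two
published ranges; multi-repeat products lighter than the nominal AFGP6
floor are still reported as AFGP6 group, the nearest class).

## Codon usage

Codon counts are accumulated at unit positions 1–3 over all classifiable
units (OTHER units excluded by default so degraded tracts do not distort
the statistics; a flag includes them). Frequencies are conditional per
position. Bias flags mark synonymous codons that are absent (others for
the same amino acid used at that position, this one never) or depleted
(share below `depleted_threshold`, default **0.02** — a design choice, the
source material gives no numeric cutoff). The classic family biases
(ACG@1 for Thr; CCC@2, CCT@2 for Pro; GCT@2 for Ala) are always examined.

`usage_distance` is the mean over the three positions of the total
variation distance between conditional frequency profiles: bounded in
[0, 1], zero iff identical, symmetric, and a metric. A position populated
in one gene but empty in the other contributes the maximum 1.

## Distances, trees, orthology

Flank distances assume pre-aligned (or equal-length, gap-free) input;
multiple sequence alignment is deliberately out of scope — simulator
output is gap-free by construction, and real flanks should be aligned with
a dedicated tool first. Columns containing a gap or N in either sequence
are deleted pairwise. The p-distance is the mismatch fraction; JC69
applies d = −(3/4)·ln(1 − 4p/3), and saturated pairs (p ≥ 0.75) are
reported at a configurable cap (default **5.0**) with a warning.

Neighbor joining is implemented in-repo (the heavier Bayesian/ML machinery
used for publication-grade trees is out of scope; NJ is exact on additive
distances, which is the regime the tests exercise). Q-criterion ties are
broken by the lexicographically smallest pair of representative labels
(the minimal leaf label under each node), so the tree is a pure function
of the distance matrix, independent of input order. The output newick
carries a trifurcating root (unrooted topology); one- and two-leaf inputs
yield degenerate trees rather than errors. Optional branch support comes
from a nonparametric bootstrap over alignment columns (default 100
replicates, seeded).

Cross-species orthology is called from tree cherries: a pair is accepted
when the two genes are sisters in at least one of the 5′/3′ trees, the
other tree does not place either gene in a cross-species cherry with a
different partner, and their C-terminus residue signatures match exactly.
Genes absent from one tree (e.g. pseudogenes whose 3′ flanks no longer
align) are judged on the remaining evidence.

`expansion_order` encodes the two rules that are actually decidable from
the data: candidate basal copies are pseudogenes whose terminal branch is
at least `basal_factor` (default 2×) the median terminal branch (dead
copies accumulate substitutions fastest), and immediate-duplicon edges are
the cross-cluster gene pairs whose shared flanking homology dominates the
runner-up by `duplicon_ratio` (default 2×). Uniform inputs produce an
empty order, not a forced story.

## Simulator

The generator emulates the mechanisms believed to have built the family:

- **slippage** — duplicates a contiguous block of units in place; block
  size is geometric with mean `slippage_block_mean` (default 2), rate
  `slippage_rate` per gene per generation (default 0.02);
- **substitution** — per-site Poisson events with a 2:1
  transition:transversion bias; when the middle base of a position-1 ACA
  codon mutates, the replacement is G (→ AGA, Arg) with probability
  `cleavage_genesis` (default 0.5) else A (→ AAA, Lys), modelling the
  single-nucleotide origin of cleavage residues from Thr codons;
- **whole-gene duplication** — copies the gene with its flanks and
  bifurcates the true gene tree (rate 0.02/gene/generation, giving
  families of roughly the observed 4–16 genes over the default 100
  generations);
- **pseudogenization** — one of the three observed defects, drawn from
  `reason_mix` (default equal weights): 5′ truncation, a 1–2 nt indel
  upstream of the repeats, or a long (default 600 nt) coding insertion.

Coding and flank substitution rates are separate knobs
(`substitution_rate`, default 10⁻⁴/site/generation; and
`flank_substitution_rate`, default 10⁻³): family trees are inferred from
flanks, so flank divergence is needed for a recoverable topology even in
"noise-free" runs where the coding sequence is kept clean. Flank lengths
default to the regions used for real gene trees (1140 bp of 5′ and 325 bp
of proximal 3′ flank). Events are drawn from a single seeded stream in a
fixed per-generation order (slippage, substitution, duplication,
pseudogenization), so a (seed, config) pair replays byte-identically; the
emitted ground truth records every gene's unit inventory, cleavage sites
(by CDS offset), status, the true tree and the full event log. Rates are
chosen for test power over a compressed 100-generation epoch — they are
not estimates of gadid mutation parameters.

What the simulator does **not** emulate: unequal crossing-over between
paralogs (hypothetical in the source material; slippage + duplication
suffice to generate the observed architecture), introns and exon
structure, selection and population dynamics, alignment gaps in flanks,
and transposable-element context. Passing recovery tests therefore shows
the pipeline is correct on the generative model's assumptions — clean
coding orientation, gap-free flanks, codon-register repeats — not that it
is robust to assembly error or structural variation in real loci.

## Problem sizes used in the validation suite

The test and acceptance runs use desk-scale problems: 1000 random CDS of
up to 600 nt for the scanner/brute-force equivalence, additive matrices up
to eight leaves (exhaustive topology search up to six), simulated families
of ~4–13 genes over 100 generations, and 20 seeded replicates for the
high-noise recovery rate. These sizes were chosen so each property is
checked exhaustively where exhaustion is feasible and stochastically with
fixed seeds elsewhere.

## Known limitations

- Exhaustive cleavage is an idealisation; in at least one species not all
  putative sites are cleaved in vivo, and partial/regulated cleavage is
  not modelled.
- Which specific Arg residues are uncleaved in vivo is unknown; predicted
  isoform inventories are upper bounds under the exhaustive assumption.
- Mass predictions exclude C-terminal extras and assume full
  glycosylation (one disaccharide per Thr).
- The ortholog rule is topology-local (cherries); deeper orthology through
  nested duplications is out of scope.
- GenBank flat-file parsing is not provided: users supply FASTA plus an
  optional coordinate TSV.
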