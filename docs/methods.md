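# Methods

## Coordinates and gene regions

All analyses use one coordinate convention: biological position 0 is the
first nucleotide of the annotated start codon and −1 the last 5'UTR
nucleotide, with no gap. Internally sequences are stored in the DNA
alphabet with 0-based half-open indices; conversion to RNA happens only at
the energetic boundary (`sdscan._thermo`).

Gene regions are extracted in coding-strand orientation (reverse-strand
genes are reverse-complemented first). The 5'UTR is trimmed at 125 nt and
clipped at the boundary of any overlapping neighbor CDS; the downstream
region after the stop codon is handled symmetrically. Genes with compound
(joined) CDS locations, CDS lengths not divisible by 3, unaccepted start
codons (default accepted set ATG/GTG/TTG) or ambiguity codes anywhere in
the extracted region are dropped with a logged warning. Matching genes
across genomes for the ≥ 50 % prevalence filter is by annotated gene name;
no orthology inference is attempted.

## The hybridization model

The 16S rRNA 3' tail is reduced to the ASD hexamer `CCUCCU`. A duplex is a
single contiguous helix of ≥ 2 canonical pairs (Watson-Crick or G·U) between
the ASD and the target window in antiparallel orientation, scored as the
duplex initiation penalty (+4.09 kcal/mol) plus the sum of nearest-neighbor
stack free energies at 37 °C. All alignments and all sub-runs of every
pairable run are evaluated (wobble stacks can be destabilizing, so a
sub-helix may beat its maximal run); the reported energy is the global
minimum, with ties broken by smaller offset, then longer helix.

Parameters (packaged in `sdscan/data/rna_stacks.tsv`): Watson-Crick stacks
from the Xia 1998 measurement set at full printed precision; G·U stacks from
the Turner 2004 tabulation (0.1 kcal/mol resolution). Terminal-AU penalties
and dangling-end terms are **off**: with terminal penalties the AGGA site
would split away from GAGG/GGAG, contradicting their observed degeneracy at
−3.60 kcal/mol, which this parameterization reproduces exactly. A
`use_terminal_au_penalty` flag restores the +0.45 kcal/mol per terminal
A·U/G·U pair for sensitivity analyses; dangles are not implemented.

Windows with no possible helix (e.g. C/U-only) are reported with a +inf
sentinel and classified SD−, since "absence" means energy above 0. For
scoring and reporting purposes the minimum *achievable* duplex energy of
such a window is the bare initiation penalty (+4.09 kcal/mol).

Classification: strict — SD+ iff ΔG < −4.4 kcal/mol, SD− iff ΔG > 0,
boundary values and the band between are excluded; relaxed — SD+ iff
ΔG ≤ 0. The strict scheme stratifies the structure profiles; the relaxed
scheme measures SD prevalence.

## The baseline folding engine

The in-repo engine (`sdscan._baseline_engine`, numba-compiled) implements a
deliberately minimal thermodynamic model: structures are nested sets of
helices (maximal runs of ≥ 2 stacked pairs — no lone pairs), hairpin loops
hold ≥ 3 unpaired nucleotides, and the only energy terms are the same
nearest-neighbor stacks used for hybridization. There are no hairpin, bulge,
internal-loop or multiloop penalties, so the open chain scores 0 and MFE is
always ≤ 0. The dynamic program's decomposition is unambiguous (each
structure has exactly one parse with every stack scored), which makes the
McCaskill-style partition-function variant exact over the same structure
space; both are verified against explicit enumeration of all structures
(MFE to 1e−9 for n ≤ 20, Boltzmann unpaired probabilities to 1e−6 for
n ≤ 30).

Accessibility is the probability that every start-codon position is
simultaneously unpaired (u = 3), computed on the single 50-nt window
centered on the codon — a documented simplification of the sliding-average
convention of local-folding tools, adopted because the averaging subtleties
are not part of any claim tested here. The optional `vienna` backend
delegates MFE to RNAfold and accessibility to the RNAplfold-style
`pfl_fold_up` routine; absolute energies differ between engines, so
analyses rely on contrasts, and the backends are required to rank a
composition-spanning 50-sequence panel with Spearman ρ ≥ 0.8.

Because the baseline model has no loop penalties it *over-stabilizes*
isolated 2-bp helices (a single −2.1 kcal/mol stack is a stable helix that
a full Turner model would reject). Two consequences are documented
elsewhere in this note: synthetic "unstructured" windows must exclude even
single stack partners, and designed sequences can rarely reach exactly
MFE = 0 unless their protein allows it.

## Profiles and the AUG comparison

`mfe_profile` slides a window (default 50 nt; 75/100 as alternates) over
biological positions −100..+100, assigning each window's MFE to its center
(offset `window // 2` from the window start). A gene contributes to a
position only when the full window fits inside its extracted region, so the
per-position n shrinks near the edges rather than being imputed; the
profile reports mean, SEM (sample SD / √n) and n per position and SD class.

`enumerate_augs` classifies every ATG in utr+cds+downstream: `start` at
position 0; `in_frame` for positions > 0, divisible by 3 and fully inside
the CDS; everything else — including upstream (UTR) ATGs, which are not
annotated starts — `out_of_frame`. Window MFE around each AUG uses the
window centered on the first AUG nucleotide. Boxplot statistics use
linear-interpolation (type-7) quantiles and Tukey whiskers clipped to the
most extreme point within 1.5 × IQR.

## Null models and shapes

The dinucleotide shuffle is the Altschul-Erickson Euler-path construction
(exact adjacent-pair counts, endpoints fixed); the dicodon shuffle is the
same construction over codon tokens, with a non-triplet remainder held
fixed. Backgrounds for sequence-motif enrichment are plain mononucleotide
permutations, 5 per input.

PSSM p-values are exact tail probabilities of the window score under i.i.d.
background, by dense convolution over column scores discretized to 1e−3
bits (verified against enumeration of all 4^w windows for w ≤ 3); zero
frequency cells are floored at −10 bits. k-mer enrichment reports the
fraction of target sequences containing each k-mer, a continuity-adjusted
background rate, a binomial upper-tail raw p, and a max-statistic
label-permutation corrected p (default 20 permutations, +1-corrected).

Abstract shapes reduce a dot-bracket structure over the alphabet `[ ] _`:
each maximal uninterrupted helix is one `[ ]`, hairpin-loop runs are
omitted (so a simple hairpin is `[]`), every other maximal unpaired run is
one `_`, and external flanks are trimmed. `keep-all` and
`drop-all-unpaired` levels are exposed. The structural null refolds each
−25..+25 region with the non-coding half dinucleotide-shuffled and the
coding half fixed, 1000 iterations by default; empirical p-values use the
+1-corrected upper tail and can never be 0. Motifs are all balanced
contiguous sub-shapes after flank trimming.

## Construct design

`DesignSpec` fixes a base sequence, a closed editable interval in
biological coordinates (e.g. −25..+20: the 25 non-coding positions and the
first 7 codons minus the immutable start), and two targets: the MFE of the
−25..+21 region and the ASD hybridization energy of the −22..−2 window
(`target_hyb=None` means "no favorable duplex"; when a finite target is
set, a windowless no-duplex state enters the score as a large finite
+10 kcal/mol stand-in). The score is the weighted sum of absolute
deviations, weights 1:1 in kcal/mol by default.

Moves: a uniform random editable position; non-coding positions take a
substitution to one of the other three bases (or, in the alternative
policy, one dicodon-preserving shuffle of the non-coding stretch read as
triplets from its 5' end); coding positions replace the containing codon
with a synonymous codon sampled proportionally to the packaged E. coli
usage table. The start codon is never mutated and single-codon amino acids
resolve to identity moves, so the protein and all flanking sequence are
invariant for every proposal, not only the final design. Acceptance is
Metropolis with geometric cooling (T0 = 2.0 score units, factor 0.999 per
iteration, 10^4 iterations by default — the schedule is the package's own
choice and fully tunable); the best-so-far sequence is returned with its
improvement trace. `design_batch` runs 100 independent seeds and returns
the 10 best, replacing manual inspection with reported diagnostics
(accessibility, GC, longest homopolymer).

## Synthetic data: what it emulates and what it does not

`generate_gene_set` draws i.i.d. backgrounds at a configurable AT content
(dinucleotide realism is deliberately omitted — planted-feature recovery
does not need it and i.i.d. keeps the truth exact), plants SD motifs from a
weighted set at the conserved 4–9 nt spacing, and guarantees SD− genes by
scrubbing G from the −22..−2 window, so SD status is exact truth rather
than probabilistic. Coding regions are valid ORFs (ATG start, terminal
stop, no internal in-frame stops).

Planted start-window modes: *structured* builds a stem-loop (default 10 bp
stem, 4 nt loop) whose first arm is the CDS 5' end, so the stem overlaps
the start codon; *unstructured* overwrites the −25..+24 window with an
A-tract carrying an optional short C-tract abutting the start codon, plus
poly-A codons downstream. That composition is the unique {A,C} arrangement
containing no `CA` dinucleotide — and `CA` is the only sequence element
that can pair the start codon's obligatory U/G under the wobble-inclusive
pair set, so under the baseline engine (which has no loop penalty to
suppress 2-bp helices) anything less strict leaves the start codon mostly
paired. The planted windows are therefore more extreme in composition than
real SD-less 5'UTRs; what passing tests show is that the *pipeline*
recovers planted contrasts faithfully, not that real UTRs look like
A-tracts. Internal AUGs are planted as the first arm of additional
stem-loops deep in the CDS, frame-controlled, with stop-free retry.

For window sizes above the planted 50 nt, every profile window necessarily
includes background, so the profile maximum is a plateau spanning the
planted region whose height varies by a few tenths of a kcal/mol with the
background composition on either side (the UTR side is 50 % AT; the CDS
side is uniform over sense codons and slightly GC-richer). Recovery tests
therefore assert that position 0 lies within one weak stack (1 kcal/mol) of
the plateau maximum — against a planted contrast of ~19 kcal/mol — rather
than demanding an exact argmax.

`generate_construct_panel` designs a ladder of constructs over target MFEs
0..−14 kcal/mol on a shared 60-nt base whose editable codons are A-rich
(so the unstructured extreme is reachable under the protein constraint),
drops rungs that miss their target by > 1.5 kcal/mol or the requested SD
status, computes start-codon accessibility for the rest, and simulates
activities: β·accessibility + N(0, σ²) without an SD, μ + N(0, σ²) with
one. By default σ is set from the realized accessibility spread so the
planted coefficient of determination is 0.6, the regime the reporter
experiments operate in. Note that at panel size n = 12 and planted
R² = 0.6 the per-draw probability of a slope p-value below 0.01 is ≈ 0.83
(noncentral-t, df = 10, ncp ≈ 4.2): individual noise draws at this design
size are *expected* to miss strict significance about one time in six.

## Numerical choices and degenerate inputs

- Energies are IEEE doubles; DP tracebacks use a 1e−9 tie tolerance and
  prefer leftmost/unpaired branches, making structures deterministic.
- Partition functions are computed unscaled; with ≤ 100-nt windows the
  Boltzmann weights stay far below overflow.
- Histogram peaks are bins ≥ both neighbors and > at least one (edges
  one-sided); all-equal inputs yield a single peak.
- Empirical p-values are +1-corrected and never zero; binomial background
  rates are continuity-adjusted to (c+1)/(n+2).
- CAI excludes the start codon, stop codons and single-codon families, and
  floors zero-RSCU weights at 1e−4 with a warning; the codon→tRNA map is a
  simplified wobble-rule table shipped as an editable TSV.
- Degenerate inputs raise `ValueError` early: empty windows, spans outside
  sequences, non-nucleotide characters, editable regions breaking codon
  boundaries, sampling beyond the population without replacement.

## Known limitations

- The baseline folding model omits all loop penalties; absolute MFEs are
  not comparable to full Turner-model values (rank agreement with the
  ViennaRNA engine is the tested contract) and tiny helices are
  over-stabilized.
- Hybridization is single-helix scanning: bulged duplexes and RNA-RNA
  co-folding are out of scope, as is the 16S rRNA beyond its tail hexamer.
- Gene matching for the prevalence filter is name-based; paralogy and
  annotation inconsistencies across genomes are not resolved.
- De novo motif discovery (EM/suffix-tree algorithms) is out of scope; this
  package supplies the scanning, background and enrichment machinery those
  tools plug into.
- The designer optimizes two scalar targets; it performs no ensemble-level
  or multi-objective design.
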