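# Methods

This document records the model behind each analysis stage, the conventions
and parameter choices, what the simulator does and does not generate, and
the known limitations.

## Coordinates and strands

All positions are 1-based and fully closed on a circular reference that
follows the J strand (the majority coding strand); the N strand is its
reverse complement. A feature whose span crosses the origin sets
`wraps_origin` and keeps `start > end`. Gene records are stored with
`start <= end` unless they wrap; for N-strand features the biological 5′
end is the *higher* coordinate (tables print N-strand genes high→low).
`coords` implements span length, overlap, gap, circular distance and
segment decomposition; every higher stage goes through it rather than
re-deriving modular arithmetic.

A transcript's along-molecule offset of a genomic position `p` from its 5′
end `t5` is `(p − t5) mod L` on J and `(t5 − p) mod L` on N. When ordering
a transcript's gene content, a gene whose 5′ entry point lies upstream of
the transcript's own 5′ end would get an offset of nearly `L`; such genes
are clamped to offset 0 (their covered part begins at the transcript 5′
end), tie-broken by exit-point offset. The classifier, the boundary
refiner and the simulator's truth labelling all share this convention.

## Reference annotations and table quirks

Two fixture tables are bundled: the DNA-sequencing-based annotation and the
transcript-refined one (genome length 14,965 bp; 13 PCGs + 22 tRNAs +
2 rRNAs; control regions CR1 3868–4052 and CR2 9478–9736 in the refined
table). Known quirks of the printed tables are preserved verbatim and
corrected at load time with logged warnings:

- the second occurrences of trnL2 (9347–9410) and trnS1 (14,903–14,965) are
  identity slips and are renamed trnL1 and trnS2;
- ATP8 is marked N-strand in the table although the accompanying text
  places only ND4, ND4L, ND5, trnY, trnP and trnH on N; the loader sets
  ATP8 to J;
- the refined trnT (9411–9477) spans 67 positions although the printed
  length column says 66; coordinates are stored verbatim (open question);
- ND4L's printed start codon (UAG) and ND4's printed stop are retained
  verbatim and surface as *validation warnings*, not errors.

Comparing the two annotations reproduces the published picture: 11 genes
plus CR2 change coordinates, and exactly six DNA-annotation overlaps are
eliminated (ND3/trnL2, trnF/srRNA, srRNA/ATP8, trnV/lrRNA, lrRNA/trnS2,
ATP8/ATP6).

## Boundary refinement

For each gene terminus, the 5′ (3′) ends of same-strand transcripts whose
*first* (*last*) sense-content gene is that gene are clustered greedily
(modal exact position absorbs everything within ±tol). A winning pileup
with support ≥ `min_support` (default 5) becomes the new boundary, subject
to category invariants: tRNAs must stay within a 50–90 nt window; PCGs,
when a genome sequence is available, must keep a valid start codon and a
complete (UAA/UAG) or truncated (U/UA) stop in frame, and codon fields are
recomputed after a valid move. Degradation scatter is filtered by the
support requirement itself. The operation is idempotent: refining an
already-refined annotation with the same evidence changes nothing.

## Transcript classification

Each mapped transcript gets exactly one label. Content = same-strand genes
covered over > 50% of their length (antisense genes additionally count when
fully covered), ordered along the transcript. End matching compares a
transcript end to the corresponding end of its terminal sense gene within
±tol (default 3 nt): a shortfall > tol is a truncation; an overhang > tol
is tolerated only when the extension does not intrude > tol into another
same-strand gene (extensions into spacers or control regions are retained
UTRs, not errors). Labels:

- `mature_mono` — one sense gene, both ends matched;
- `mature_multi` — a recognized uncleaved unit (ATP8/ATP6, ND4/ND4L,
  COI/ND3), both ends matched;
- `polycistronic` — several sense genes, both ends matched;
- `degraded` — sense content with an unmatched end (truncation recorded as
  5prime / 3prime / both);
- `antisense` — only antisense content;
- `ncRNA_CR` — no gene content, majority of the molecule inside a control
  region.

UTR detection applies to mature mRNAs only and reports per-end UTR lengths
and the poly(A)-site position when a tail is present.

### Cleavage direction

tRNA punctuation removes tRNAs either 3′→5′ ("reverse") or 5′→3′
("forward"). A processing intermediate votes for a direction only when it
shows both (i) a flush end at the cut site of an *absent* flanking tRNA and
(ii) at least one *uncleaved* internal same-strand tRNA junction — fully
processed molecules witness neither direction and are silent. Under
all-reverse or all-forward simulation this evidence is 100% pure.

## Coverage and expression

Per-base strand-specific depth; every transcript increments every position
it covers (wrapping where flagged), so total depth always equals the sum of
transcript lengths — an exact conservation law used as a test oracle.
Expression of a gene or merged unit is its mean per-base depth on its own
coding strand; ranking is depth-descending with deterministic alphabetical
tie-breaks and an explicit `tied` flag. bedGraph output is 0-based
half-open as the format requires.

## Isoforms and degradation orientation

An isoform is a reproducible end-pair species: greedy clustering repeatedly
takes the modal exact (5′, 3′) pair and absorbs transcripts within ±tol at
*both* ends; clusters need support ≥ 5. The ND2 worked example — ends
(5678, 6659) — has length 982 bp. A second printed ND2 isoform is reported
as 899 bp, which does not follow from any printed end pair; it is left as
an open question and not asserted anywhere. Transcripts matching clusters
at one end only are degradation candidates; whether the 5′ or 3′ end
varies gives the degradation orientation.

## Regulatory inference

TIS/TTS candidates are transcript-end pileups that gene boundaries cannot
explain: ends of non-degraded transcripts are clustered per strand and end
type; pileups within ±tol of any annotated record boundary (cleavage
products) are discarded, as are pileups below `min_site_support`
(default 3). One further exclusion: a 3′ pileup sitting exactly one step
upstream of a detected same-strand 5′ pileup is discarded, because a
polymerase that reads through every terminator stops when it runs back
into its own initiation site after a full circle — such ends mark the
origin of a transcription unit, not a terminator. *Limitation:* a genuine
TTS located immediately upstream of a TIS would be suppressed by this
rule; the two are observationally indistinguishable in end data.

Control-region sequence scanning finds poly-A/poly-T runs, G(A)nT, A(T)n
and (TA)n motifs by regular expression and perfect stem-loops by
reverse-complement self-matching (no thermodynamic folding). CR1/CR2
repeat detection seeds exact 12-mers and extends ungapped while running
identity stays ≥ 0.9, reporting maximal pairs ≥ 50 bp.

The transcription-model summary lists ordered TIS/TTS per strand, whether
each control region is fully covered by transcription on each strand, and
which same-strand gene blocks lack any detected antisense transcript.

## Gene-order comparison

Adjacency is unordered and strand-agnostic: two genes are adjacent when
consecutive on the circle in either orientation. Control regions are not
genes but act as adjacency *barriers* — genes separated by a CR are not
adjacent. Shared adjacency blocks are maximal chains of adjacencies present
in both circular orders; strand flips are genes coded on different strands
in the two orders; breakpoint distance counts adjacencies of one order
missing from the other (symmetric for equal gene sets). Against the
bundled ancestral insect order, the *S. houjii* arrangement shares 6 blocks
covering 14 genes with 8 strand flips. Correctness is checked against an
independent union-find oracle over shared adjacencies on random circular
orders (each gene touches ≤ 2 shared adjacencies, so every multi-gene
component is exactly one conserved chain).

## The simulator and study conditions

`simulate` is a forward model whose defaults
(`src/mitoscribe/data/shoujii_like.yaml`) are the study conditions used by
all validation: 5,000 molecules; two TIS/TTS pairs per strand inside CR1
and CR2 plus a third N-strand TIS at 13,864 inside the antisense of lrRNA;
strand strengths reproducing a slight N-over-J excess; cleavage completion
0.9 with 90% reverse direction; 20% of molecules exonucleolytically
trimmed from one end (geometric, mean 150 nt); poly(A) ~ N(30, 10);
integer-rounded Gaussian end noise σ = 1; minimum length 20 nt; seed 42.

A molecule is born at a TIS drawn proportionally to strength, terminates
at the first TTS whose read-through draw fails (hard stop after one full
circle), is cleaved at same-strand tRNA junction gaps in direction order
with stalling at the first failed completion draw, one fragment is sampled
uniformly, optionally degraded, then noised and tailed. Every emitted
molecule carries a `TruthRecord`.

**Truth labels are observational**: the class label is defined over the
exact pre-noise geometry under the study tolerance, exactly mirroring the
classifier's definitions (implemented independently but sharing the
conventions above). A trim that leaves no geometric signature — e.g.
confined to a retained UTR, or on a CR/antisense fragment — does not make
the molecule "degraded"; the generative facts live in
`TruthRecord.degraded_end` / `trim_len` instead. This is what makes the
noise-free label-recovery check exact (a differential test of two
implementations) rather than a fuzzy match against unobservable history.

### Generator scope and limitations

- Cleavage happens only at same-strand tRNA junctions. mRNA 3′ ends that
  abut a control region (e.g. COIII | CR1 at 3867/3868) therefore arise
  only via termination, never via processing; running boundary refinement
  on fully simulated data moves such boundaries to the TTS, which is the
  correct answer *for that data*. Refinement against the published-style
  evidence is exercised with curated flush end pileups.
- Genes not flanked by a same-strand tRNA on their 5′ side (e.g. ND2,
  released inside a CYTB/astrnY/ND2 precursor) never appear as mature
  monocistrons in simulation.
- Degradation ends can pile up by chance anywhere. The zero-false-call
  guarantee for TIS/TTS recovery therefore holds in the clean regime (no
  end noise, no degradation); with degradation on, low-support chance
  pileups of trimmed ends of abundant species can appear (observed: a
  support-4 pileup 4 nt downstream of a true TIS). No caller can exclude
  these from end data alone.
- No sequencing-level artifacts (chimeras, mapping error, strand
  misassignment), no RNA editing, no secondary-structure-aware processing.

## Numerical and implementation choices

- Tolerance ±3 nt and support thresholds (5 for boundaries/isoforms, 3 for
  sites) are the study defaults everywhere; no stage has hidden
  stage-specific thresholds.
- All clustering is greedy-modal with deterministic tie-breaks (higher
  support, then smaller coordinate), so results are independent of input
  order.
- All randomness flows from a single `numpy` Generator seeded from the
  scenario; reruns are byte-identical.
- Coverage uses int64 accumulation; no floating-point accumulation is used
  where exact conservation is asserted.

## Open questions

- Refined trnT spans 67 positions vs a printed length of 66.
- The second printed ND2 isoform length (899 bp) matches no printed end
  pair.
- The advisory external comparison against *Neohydatothrips samayunkur*
  (MF991901) requires that genome's annotation and is not part of the test
  suite.
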