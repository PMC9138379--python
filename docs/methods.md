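# Methods

## Assay model

The package models single-strand clone-based bisulfite sequencing. All
conversion, PCR and calling act on the top strand of the supplied
locus: the primer pairs this assay style uses are designed against the
converted top strand, and a bottom-strand assay would be a separate
primer set. Hemimethylation across strands is therefore out of scope.

Bisulfite chemistry is reduced to one parameter. An unmethylated C
deaminates (reads as T) with probability `efficiency`; 5mC is fully
protected. Inappropriate conversion of 5mC is fixed at zero — there is
no reliable estimate for it in this assay class, and a second knob
would be unidentifiable from 10 clones. Consequently every false
positive in the simulation comes from conversion failure or sequencing
error, and every false negative from sequencing error alone.

Cytosine contexts follow the plant convention: CpG when the next base
is G; CpHpG when positions +1 ∈ {A,C,T} and +2 = G; CpHpH when both
are in {A,C,T}. A context that runs past the locus end or touches an N
is *ambiguous*: such cytosines are never called and never counted in
denominators, which keeps the partition invariant
D(CpG)+D(CpHpG)+D(CpHpH) = classifiable Cs exact.

## Coordinates and ambiguity codes

All coordinates are 0-based half-open (BED convention); 1-based text
appears only in formatted reports. IUPAC matching is subset-based: a
window character matches a pattern code iff its expansion is contained
in the code's expansion. A reference N therefore matches only a
pattern N — ambiguous reference bases never satisfy a concrete pattern
base, and an N is never a callable cytosine.

## CpG islands

Islands use the Gardiner-Garden–Frommer criteria with the defaults
published for the standard bisulfite-primer design tool: window 100 bp,
step 1 bp, minimum merged length 100 bp, GC ≥ 0.50, CpG obs/exp ≥ 0.60,
all overridable. Passing windows are merged when they overlap or abut;
merged regions shorter than the minimum are dropped; GC and obs/exp are
then recomputed on the merged region itself rather than averaged over
windows, so the reported statistics are properties of the reported
interval. Because CG is its own reverse complement, a single top-strand
pass suffices. The merge of step-1 windows equals maximal-run
enumeration, which is how the test oracle recomputes it.

## In-silico PCR and primer footprints

Primer placement matches the forward primer against the fully
converted (all-unmethylated) top strand and the reverse primer against
its reverse complement, with degenerate R/Y codes matching per IUPAC
and an optional per-primer mismatch budget (default 0). Exactly one
compatible site pair must remain; zero is a no-product error and
several a non-specificity error listing the sites — mirroring what a
gel would show.

Cytosines under either primer footprint are excluded from calling
*and* from denominators: the primer oligo overwrites the template
state there, so those sites are unobservable. Published per-gene
denominators from this assay may include footprint cytosines and may
sum overlapping amplicons differently; `count_potential_sites` exposes
`include_primer_footprint` for reconciliation, and overlapping
amplicons are always deduplicated by reference position (union, not
sum).

## Clone alignment and calling

Clones are globally aligned to the *unconverted* amplicon sequence
(Bio.Align.PairwiseAligner) with an asymmetric substitution matrix:
match +1, mismatch −1, gap open −3, gap extend −1, and reference-C vs
read-T scored as a match — the bisulfite asymmetry. Identity counts
C/T columns as matches; clones below 90% identity, or outside ±20% of
the amplicon length, are rejected and logged rather than failing the
run (matching how unusable Sanger clones are dropped at the bench).
These thresholds are ordinary Sanger-clone tolerances, not fitted
values. On substitution-only reads the alignment reduces to the
identity mapping, which the tests assert against a direct
position-by-position oracle.

Calling is per clone and per classifiable reference C outside the
primer footprints: read C → methylated, read T → unmethylated,
anything else (gap, other base) → uncallable. Conversion-efficiency QC
is deliberately report-only and never filters calls: in plants,
non-CpG methylation is biologically real, so an excess of retained
non-CpG cytosines cannot be used as a failed-conversion proxy without
destroying genuine CpHpH signal.

A *stable* mark is a position methylated in at least `min_fraction` of
clones (default 1.0 — every clone), with at least one methylated clone
required regardless, so a threshold of 0 degenerates to "ever
methylated". Motif status uses `min_clones = 1` by default — one
methylated clone anywhere inside the element marks it "+" — because the
single-clone convention is the permissive reading of published +/−
motif tables; the flag is exposed for the stable-mark reading.
Motifs are scanned on both strands by default (element orientation
annotations are inconsistent across catalogues), and an element's
status counts methylated cytosines of any context, since non-canonical
CpHpH marks do land on regulatory elements.

## Synthetic data generator

The generator emulates the study design this pipeline targets: one
locus of ~1600 bp (promoter plus gene start), two planted CpG islands,
two tissues with 10 clones each, context-dependent methylation rates,
imperfect conversion, and Sanger-scale read error.

- **Background sequence** is a first-order chain at GC 0.44 with
  P(G | previous C) scaled by 0.35, reproducing the CpG depletion
  (obs/exp well below 1) of genomic background so that planted islands
  are detectable against it rather than by fiat.
- **Islands** are rejection-sampled i.i.d. segments at the target GC
  until the realized GC and obs/exp meet their targets (bounded retries,
  then a feasibility error). Defaults: 220 bp at GC 0.62/obs-exp 0.75
  and 260 bp at GC 0.60/0.70 — modest, realistic plant islands.
- **Methylomes**: every classifiable C is methylated independently
  with its context's rate. Defaults make the coleoptile unmethylated
  and the root weakly methylated at CpG 0.14, CpHpG 0.05, CpHpH 0.01 —
  the k/D ratio scale of a weakly silenced promoter in this assay
  class (≈7/50, 2/42, 1/118).
- **Clones**: each clone independently converts the amplicon region at
  `efficiency` 0.99 (a typical commercial-kit figure) and then applies
  substitution errors at 10⁻³ per base (finished Sanger quality).
  Reads are full length: no truncation, chimeras, PCR or cloning bias.
- **Primer design** for the synthetic assay takes the converted
  substrings flanking a ~400 bp product around the first island,
  growing the primers from 24 nt until the pair is unique on the
  template.

Everything is a pure function of (params, seed); per-stage seeds are
spawned from the master seed via `numpy.random.SeedSequence`.

What passing on this generator does *not* show: robustness to indels
(the error model is substitution-only, though the aligner handles
gaps), bisulfite over-conversion of 5mC, PCR/cloning bias among
molecules, or chromatogram-level basecall quality. Results on real
clone sets depend on those factors too.

## Verification design

Every scanner has an independent brute-force oracle in the test suite:
islands against naive per-window recounting with maximal-run merging;
motif scanning against full IUPAC expansion plus substring search;
context classification and denominators against direct enumeration;
alignment against position-by-position comparison on indel-free reads.
Property tests (hypothesis, seeded) cover reverse-complement
involution and subset-matching semantics.

The headline whole-chain checks, also recomputed by
`scripts/acceptance.py`:

1. **Lossless recovery** — at efficiency 1.0 and error 0, called
   methylomes equal the generating truth exactly (sensitivity =
   specificity = 1.0) across 20 replicate seeds.
2. **Denominator correctness** — potential-site counts equal
   enumeration on 100 random 300–800 bp loci, and contexts partition
   the classifiable Cs.
3. **Island oracle** — agreement on 50 random loci up to 2 kb.
4. **Motif oracle** — agreement for the full 29-motif catalogue on
   random 1 kb loci.
5. **Noise degradation** — at efficiency 0.95 / error 0.005, pooled
   clone-level CpG sensitivity over 50 replicates lies inside the
   central 99.9% band of Binomial(n, 1−e): a methylated C is protected
   from conversion, so only a sequencing error (rate e) can knock out
   its C readout.

Replicate counts (20/100/50/3×29/50) keep the full suite under half a
minute while leaving the binomial envelope in check 5 narrow enough to
catch a systematic calling or alignment defect.

## Known limitations

Single-strand, single-locus assays only; no short-read (WGBS/RRBS)
support; no melting-temperature model for primers (annealing
temperature is carried as metadata); island calling replicates the
criteria, not any specific web tool's unpublished merge rules, so
boundary-level agreement with such tools is not guaranteed; published
denominator conventions (footprint inclusion, overlap handling) vary,
see the footprint toggle above.
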