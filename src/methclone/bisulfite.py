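"""In-silico bisulfite assay: conversion, degenerate-primer PCR, clone
alignment, and per-cytosine methylation calling in three contexts.

The assay mirrors clone-based bisulfite Sanger sequencing of a single
(top) strand: sodium bisulfite deaminates unmethylated cytosine to
uracil (read as T) while 5-methylcytosine stays C; PCR primers designed
against the converted template delimit the observable amplicon; each
plasmid clone is one molecule, aligned back to the *unconverted*
reference with C/T asymmetric scoring; every reference cytosine between
the primer footprints is then called methylated (read C), unmethylated
(read T) or uncallable (gap / other base). Cytosines are classified as
CpG, CpHpG or CpHpH (H = A, C or T), the three plant methylation
contexts.

Sites under primer footprints are excluded from calls and denominators:
the primer sequence overwrites the template's methylation state there.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .seq_core import (
    Interval,
    ReferenceLocus,
    hamming_iupac,
    revcomp,
)

CONTEXTS = ("CpG", "CpHpG", "CpHpH")
H_BASES = frozenset("ACT")


class NoProductError(RuntimeError):
    """Primer pair produces no amplicon on the template."""


class NonSpecificPrimerError(RuntimeError):
    """Primer pair matches more than one site pair on the template."""

    def __init__(self, message: str, sites: list[tuple[int, int]]):
        super().__init__(message)
        self.sites = sites


class CloneRejectedError(RuntimeError):
    """Clone alignment identity fell below the acceptance threshold."""


@dataclass(frozen=True)
class MethylationProfile:
    """Per-position methylation state for every cytosine on the top strand.

    ``states`` maps 0-based C positions to True (methylated) / False.
    """

    locus_id: str
    states: Mapping[int, bool]

    def is_methylated(self, pos: int) -> bool:
        return bool(self.states.get(pos, False))

    @property
    def methylated_positions(self) -> frozenset[int]:
        return frozenset(p for p, m in self.states.items() if m)


@dataclass(frozen=True)
class BisulfitePrimerPair:
    """A primer pair designed against the converted top strand.

    Degenerate bases (R on the reverse primer, Y on the forward) cover
    template cytosines whose converted readout depends on methylation.
    ``annealing_c`` is metadata only; no melting-temperature model.
    """

    gene: str
    forward: str
    reverse: str
    expected_product_bp: int
    annealing_c: float | None = None

    def __post_init__(self) -> None:
        if len(self.forward) < 15 or len(self.reverse) < 15:
            raise ValueError(f"{self.gene}: primers must be >= 15 nt")
        if self.expected_product_bp <= len(self.forward) + len(self.reverse):
            raise ValueError(
                f"{self.gene}: expected product must exceed combined primer length"
            )


@dataclass(frozen=True)
class Amplicon:
    """The primer-delimited observable region (primer-inclusive interval)."""

    locus_id: str
    interval: Interval
    primer_pair: BisulfitePrimerPair

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def forward_footprint(self) -> Interval:
        s = self.interval.start
        return Interval(s, s + len(self.primer_pair.forward))

    @property
    def reverse_footprint(self) -> Interval:
        e = self.interval.end
        return Interval(e - len(self.primer_pair.reverse), e)

    def in_footprint(self, pos: int) -> bool:
        return self.forward_footprint.contains(pos) or self.reverse_footprint.contains(pos)


@dataclass(frozen=True)
class CloneRead:
    """One sequenced plasmid clone (a single bisulfite-PCR molecule)."""

    clone_id: str
    sample: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"clone {self.clone_id}: empty sequence")


@dataclass
class CloneAlignment:
    """Global alignment of a clone to the unconverted amplicon region.

    ``ref_to_read`` maps each reference position inside the amplicon to the
    aligned read base, or None where the read has a gap.
    """

    clone_id: str
    sample: str
    amplicon: Amplicon
    ref_to_read: dict[int, str | None]
    mismatches: int  # non-bisulfite mismatches only
    gaps: int
    identity: float


@dataclass(frozen=True)
class MethylationCall:
    ref_pos: int
    context: str  # CpG | CpHpG | CpHpH
    status: str  # methylated | unmethylated | uncallable
    clone_id: str
    sample: str


@dataclass(frozen=True)
class ContextCounts:
    """Potential (denominator) cytosine counts per context in the assayed region."""

    cpg: int
    chg: int
    chh: int

    def total(self) -> int:
        return self.cpg + self.chg + self.chh

    def by_context(self) -> dict[str, int]:
        return {"CpG": self.cpg, "CpHpG": self.chg, "CpHpH": self.chh}


@dataclass(frozen=True)
class CloneSummary:
    """Per-context clone grouping in the compact "k/D in m" report form."""

    gene: str
    sample: str
    n_clones: int
    denominators: ContextCounts
    # context -> sorted list of (k methylated sites, m clones)
    groups: Mapping[str, tuple[tuple[int, int], ...]]

    def format_cell(self, context: str) -> str:
        d = self.denominators.by_context()[context]
        return "; ".join(f"{k}/{d} in {m}" for k, m in self.groups[context])


def convert_bisulfite(
    locus: ReferenceLocus,
    profile: MethylationProfile,
    efficiency: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> str:
    """Simulate sodium-bisulfite conversion of the top strand.

    Each unmethylated C deaminates to T with probability ``efficiency``
    (independent Bernoulli draws); methylated Cs are protected and stay C.
    ``efficiency`` 1.0 is fully deterministic.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = list(locus.sequence)
    c_positions = [i for i, b in enumerate(out) if b == "C"]
    unmeth = [p for p in c_positions if not profile.is_methylated(p)]
    if efficiency >= 1.0:
        converted = np.ones(len(unmeth), dtype=bool)
    else:
        converted = rng.random(len(unmeth)) < efficiency
    for p, conv in zip(unmeth, converted):
        if conv:
            out[p] = "T"
    return "".join(out)


def classify_context(locus: ReferenceLocus, pos: int) -> str | None:
    """Classify the cytosine at ``pos`` as CpG, CpHpG or CpHpH.

    Returns None ("ambiguous") when the context extends past the locus end
    or touches an N. Raises if the position does not hold a C.
    """
    seq = locus.sequence
    if seq[pos] != "C":
        raise ValueError(f"position {pos} holds {seq[pos]!r}, not C")
    if pos + 1 >= len(seq):
        return None
    nxt = seq[pos + 1]
    if nxt == "G":
        return "CpG"
    if nxt not in H_BASES:
        return None  # N at pos+1
    if pos + 2 >= len(seq):
        return None
    nxt2 = seq[pos + 2]
    if nxt2 == "G":
        return "CpHpG"
    if nxt2 in H_BASES:
        return "CpHpH"
    return None


def fully_converted_top(locus: ReferenceLocus) -> str:
    """The top strand converted under the all-unmethylated assumption (C->T)."""
    profile = MethylationProfile(locus.id, {})
    return convert_bisulfite(locus, profile, efficiency=1.0)


def find_primer_sites(
    pair: BisulfitePrimerPair,
    converted_top: str,
    max_mismatch: int = 0,
) -> list[tuple[int, int]]:
    """Candidate (forward start, reverse end) pairs on the converted template.

    The forward primer is matched against the converted top strand, the
    reverse primer against its reverse complement; degenerate R/Y codes
    match per IUPAC. Only non-overlapping pairs with forward before
    reverse are reported.
    """
    fwd, rev = pair.forward.upper(), pair.reverse.upper()
    fwd_starts = [
        i
        for i in range(len(converted_top) - len(fwd) + 1)
        if hamming_iupac(fwd, converted_top[i : i + len(fwd)]) <= max_mismatch
    ]
    rc = revcomp(converted_top)
    n = len(converted_top)
    rev_ends = [
        n - j
        for j in range(len(rc) - len(rev) + 1)
        if hamming_iupac(rev, rc[j : j + len(rev)]) <= max_mismatch
    ]
    return [
        (fs, re_)
        for fs in fwd_starts
        for re_ in rev_ends
        if fs + len(fwd) <= re_ - len(rev)
    ]


def in_silico_pcr(
    pair: BisulfitePrimerPair,
    locus: ReferenceLocus,
    max_mismatch: int = 0,
) -> Amplicon:
    """Run the primer pair against the fully converted top strand of ``locus``.

    Exactly one candidate site pair must remain; zero raises
    :class:`NoProductError`, several raise :class:`NonSpecificPrimerError`.
    """
    sites = find_primer_sites(pair, fully_converted_top(locus), max_mismatch)
    if not sites:
        raise NoProductError(
            f"{pair.gene}: no product on {locus.id} (max_mismatch={max_mismatch})"
        )
    if len(sites) > 1:
        raise NonSpecificPrimerError(
            f"{pair.gene}: {len(sites)} candidate products on {locus.id}: {sites}",
            sites,
        )
    start, end = sites[0]
    return Amplicon(locus_id=locus.id, interval=Interval(start, end), primer_pair=pair)


def _bisulfite_aligner(match: float = 1.0, mismatch: float = -1.0,
                       gap_open: float = -3.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    """Global aligner whose substitution matrix scores ref-C vs read-T as match."""
    alphabet = "ACGTN"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            mat[a, b] = match if a == b else mismatch
    # bisulfite asymmetry: a reference C may legitimately read as T
    mat["C", "T"] = match
    # N is uninformative on either side
    for a in alphabet:
        mat["N", a] = 0.0
        mat[a, "N"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_clone(
    read: CloneRead,
    locus: ReferenceLocus,
    amplicon: Amplicon,
    min_identity: float = 0.90,
    length_tolerance: float = 0.20,
) -> CloneAlignment:
    """Globally align a clone to the unconverted amplicon region.

    Scoring treats read T opposite reference C as a match (the bisulfite
    asymmetry); identity counts those columns as matches too. Clones whose
    length is outside ``±length_tolerance`` of the amplicon length, or
    whose identity falls below ``min_identity``, are rejected.
    """
    ref_seq = locus.sequence[amplicon.interval.start : amplicon.interval.end]
    lo = len(ref_seq) * (1 - length_tolerance)
    hi = len(ref_seq) * (1 + length_tolerance)
    if not lo <= len(read.sequence) <= hi:
        raise CloneRejectedError(
            f"clone {read.clone_id}: length {len(read.sequence)} outside "
            f"±{length_tolerance:.0%} of amplicon length {len(ref_seq)}"
        )
    aligner = _bisulfite_aligner()
    aln = aligner.align(ref_seq, read.sequence.upper())[0]

    offset = amplicon.interval.start
    ref_to_read: dict[int, str | None] = {
        offset + i: None for i in range(len(ref_seq))
    }
    matches = 0
    mismatches = 0
    aligned_cols = 0
    for (rs, re_), (qs, qe) in zip(*aln.aligned):
        for k in range(re_ - rs):
            ref_base = ref_seq[rs + k]
            read_base = read.sequence[qs + k].upper()
            ref_to_read[offset + rs + k] = read_base
            aligned_cols += 1
            if ref_base == read_base or (ref_base == "C" and read_base == "T"):
                matches += 1
            else:
                mismatches += 1
    gaps = len(ref_seq) - aligned_cols
    identity = matches / len(ref_seq) if ref_seq else 0.0
    if identity < min_identity:
        raise CloneRejectedError(
            f"clone {read.clone_id}: identity {identity:.3f} < {min_identity}"
        )
    return CloneAlignment(
        clone_id=read.clone_id,
        sample=read.sample,
        amplicon=amplicon,
        ref_to_read=ref_to_read,
        mismatches=mismatches,
        gaps=gaps,
        identity=identity,
    )


def callable_positions(locus: ReferenceLocus, amplicon: Amplicon) -> list[tuple[int, str]]:
    """Context-classifiable reference-C positions in the amplicon outside primers."""
    out = []
    for pos in range(amplicon.interval.start, amplicon.interval.end):
        if locus.sequence[pos] != "C" or amplicon.in_footprint(pos):
            continue
        ctx = classify_context(locus, pos)
        if ctx is not None:
            out.append((pos, ctx))
    return out


def call_methylation(aln: CloneAlignment, locus: ReferenceLocus) -> list[MethylationCall]:
    """Call every classifiable reference C in the amplicon, outside primers.

    Read C -> methylated, read T -> unmethylated, gap or any other base ->
    uncallable.
    """
    calls = []
    for pos, ctx in callable_positions(locus, aln.amplicon):
        base = aln.ref_to_read.get(pos)
        if base == "C":
            status = "methylated"
        elif base == "T":
            status = "unmethylated"
        else:
            status = "uncallable"
        calls.append(
            MethylationCall(
                ref_pos=pos,
                context=ctx,
                status=status,
                clone_id=aln.clone_id,
                sample=aln.sample,
            )
        )
    return calls


def count_potential_sites(
    locus: ReferenceLocus,
    amplicons: Sequence[Amplicon],
    include_primer_footprint: bool = False,
) -> ContextCounts:
    """Denominators: distinct classifiable C positions in the amplicon union.

    Positions covered by several overlapping amplicons count once. Primer
    footprints are excluded by default (the primer overwrites the template
    state there); ``include_primer_footprint`` reinstates them for
    reconciliation against reports that counted them.
    """
    positions: dict[int, str] = {}
    for amp in amplicons:
        if amp.locus_id != locus.id:
            raise ValueError(f"amplicon on {amp.locus_id}, locus is {locus.id}")
        for pos in range(amp.interval.start, amp.interval.end):
            if locus.sequence[pos] != "C":
                continue
            if not include_primer_footprint and all(
                a.in_footprint(pos)
                for a in amplicons
                if a.interval.contains(pos)
            ):
                continue
            ctx = classify_context(locus, pos)
            if ctx is not None:
                positions[pos] = ctx
    counts = Counter(positions.values())
    return ContextCounts(
        cpg=counts.get("CpG", 0),
        chg=counts.get("CpHpG", 0),
        chh=counts.get("CpHpH", 0),
    )


def summarize_clones(
    calls: Iterable[MethylationCall],
    denominators: ContextCounts,
    n_clones: int,
    gene: str = "",
    sample: str = "",
) -> CloneSummary:
    """Group clones by their per-context methylated-site count k.

    Produces the compact per-context groups "k/D in m" (k methylated of D
    potential sites, in m of the n clones), sorted by k. Every clone that
    contributed calls is counted; clones named in ``calls`` must number at
    most ``n_clones`` (clones with zero methylated sites still appear if
    they emitted any call).
    """
    calls = list(calls)
    clone_ids = sorted({c.clone_id for c in calls})
    if len(clone_ids) > n_clones:
        raise ValueError(
            f"{len(clone_ids)} distinct clones in calls but n_clones={n_clones}"
        )
    per_clone_k: dict[str, dict[str, int]] = {
        cid: {ctx: 0 for ctx in CONTEXTS} for cid in clone_ids
    }
    for c in calls:
        if c.status == "methylated":
            per_clone_k[c.clone_id][c.context] += 1
    groups: dict[str, tuple[tuple[int, int], ...]] = {}
    denoms = denominators.by_context()
    for ctx in CONTEXTS:
        ks = Counter(per_clone_k[cid][ctx] for cid in clone_ids)
        # clones absent from calls (e.g. zero callable sites) count as k=0
        missing = n_clones - len(clone_ids)
        if missing:
            ks[0] += missing
        for k in ks:
            if k > denoms[ctx]:
                raise ValueError(f"k={k} exceeds denominator {denoms[ctx]} for {ctx}")
        groups[ctx] = tuple(sorted(ks.items()))
    if sample == "" and calls:
        sample = calls[0].sample
    return CloneSummary(
        gene=gene,
        sample=sample,
        n_clones=n_clones,
        denominators=denominators,
        groups=groups,
    )


def stable_sites(
    calls: Iterable[MethylationCall],
    n_clones: int,
    min_fraction: float = 1.0,
) -> list[int]:
    """Positions methylated in at least ``min_fraction`` of clones.

    The default 1.0 is the "stable mark" notion (methylated in every
    clone); a site must be methylated in at least one clone regardless, so
    ``min_fraction=0.0`` degenerates to every ever-methylated site.
    """
    meth_clones: dict[int, set[str]] = defaultdict(set)
    for c in calls:
        if c.status == "methylated":
            meth_clones[c.ref_pos].add(c.clone_id)
    return sorted(
        pos
        for pos, clones in meth_clones.items()
        if len(clones) >= max(1, min_fraction * n_clones)
    )


def read_primer_table(path: str | Path) -> list[BisulfitePrimerPair]:
    """Read a primer TSV (columns: gene, forward, reverse, expected_bp, annealing_c)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "forward", "reverse", "expected_bp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    pairs = []
    for _, row in df.iterrows():
        pairs.append(
            BisulfitePrimerPair(
                gene=row["gene"],
                forward=row["forward"].strip().upper(),
                reverse=row["reverse"].strip().upper(),
                expected_product_bp=int(row["expected_bp"]),
                annealing_c=float(row["annealing_c"]) if "annealing_c" in df.columns else None,
            )
        )
    return pairs


def calls_to_frame(calls: Iterable[MethylationCall], locus_id: str) -> pd.DataFrame:
    """Tidy per-call table (one row per clone x position)."""
    return pd.DataFrame(
        [
            {
                "locus": locus_id,
                "position": c.ref_pos,
                "context": c.context,
                "status": c.status,
                "clone_id": c.clone_id,
                "sample": c.sample,
            }
            for c in calls
        ]
    )
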