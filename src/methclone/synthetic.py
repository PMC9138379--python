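"""Synthetic promoter/methylome/clone-read generator.

Emulates the statistical structure of a clone-based bisulfite study of a
plant promoter: a GC-structured reference locus with planted CpG islands
and planted cis-regulatory motifs; per-tissue methylomes in which every
cytosine is methylated independently with a context-specific probability
(CpG >> CpHpG > CpHpH, differing between the two tissues); and, per
tissue, a small set of cloned Sanger reads produced by bisulfite
conversion at configurable efficiency plus independent per-base
sequencing error.

Defaults emulate the study conditions the pipeline targets: a ~1.6 kb
locus (promoter plus gene start), two planted islands, two tissues
("coleoptile" essentially unmethylated, "root" methylated at rates
CpG 0.14 / CpHpG 0.05 / CpHpH 0.01 — the ratio scale of a weakly
silenced promoter), 10 clones per tissue, conversion efficiency 0.99,
and Sanger-scale error 1e-3.

Everything is deterministic given (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .bisulfite import (
    Amplicon,
    BisulfitePrimerPair,
    CloneRead,
    MethylationProfile,
    NonSpecificPrimerError,
    classify_context,
    convert_bisulfite,
    fully_converted_top,
    in_silico_pcr,
)
from .cpg_islands import gc_fraction, obs_exp_cpg
from .motifs import MotifDefinition
from .seq_core import IUPAC_EXPANSION, Interval, ReferenceLocus

BASES = np.array(list("ACGT"))


class FeasibilityError(RuntimeError):
    """An island spec could not be satisfied within the retry budget."""


@dataclass(frozen=True)
class IslandSpec:
    """A region to be drawn with elevated GC and CpG obs/exp."""

    start: int
    length: int
    gc: float = 0.60
    obs_exp: float = 0.70


@dataclass(frozen=True)
class PlantedMotif:
    motif: MotifDefinition
    start: int
    strand: str = "+"


@dataclass(frozen=True)
class SimulationParams:
    """Study-shaped simulation conditions; see module docstring for defaults."""

    locus_length: int = 1600
    background_gc: float = 0.44
    #: factor multiplying P(G | previous C) in background sequence; < 1 gives
    #: the CpG depletion typical of plant promoter background, so planted
    #: islands stand out against it
    background_cpg_depletion: float = 0.35
    island_specs: tuple[IslandSpec, ...] = (
        IslandSpec(start=350, length=220, gc=0.62, obs_exp=0.75),
        IslandSpec(start=900, length=260, gc=0.60, obs_exp=0.70),
    )
    planted_motifs: tuple[PlantedMotif, ...] = ()
    # per tissue, per context methylation probabilities
    methylation_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "coleoptile": {"CpG": 0.0, "CpHpG": 0.0, "CpHpH": 0.0},
            "root": {"CpG": 0.14, "CpHpG": 0.05, "CpHpH": 0.01},
        }
    )
    n_clones: int = 10
    conversion_efficiency: float = 0.99
    sequencing_error: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for tissue, rates in self.methylation_rates.items():
            for ctx, p in rates.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{tissue}/{ctx}: rate {p} outside [0, 1]")
        for spec in self.island_specs:
            if spec.start < 0 or spec.start + spec.length > self.locus_length:
                raise ValueError(f"island spec {spec} outside locus bounds")
        for pm in self.planted_motifs:
            if pm.start < 0 or pm.start + len(pm.motif.pattern) > self.locus_length:
                raise ValueError(f"planted motif {pm.motif.name} outside locus bounds")
        if not 0.0 <= self.conversion_efficiency <= 1.0:
            raise ValueError("conversion_efficiency outside [0, 1]")
        if not 0.0 <= self.sequencing_error <= 1.0:
            raise ValueError("sequencing_error outside [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """The generator's ground truth: locus, per-tissue methylomes, planted features."""

    locus: ReferenceLocus
    profiles: Mapping[str, MethylationProfile]
    planted_islands: tuple[Interval, ...]
    planted_motifs: tuple[PlantedMotif, ...]
    params: SimulationParams


def _draw_segment(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _draw_background(
    rng: np.random.Generator, length: int, gc: float, cpg_depletion: float
) -> str:
    """First-order chain at target GC with P(G | prev C) scaled down.

    Reproduces the CpG depletion (observed/expected well below 1) of
    genomic background outside islands.
    """
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    after_c = base_p.copy()
    after_c[2] *= cpg_depletion  # index 2 = G
    after_c /= after_c.sum()
    out = []
    prev = ""
    for _ in range(length):
        p = after_c if prev == "C" else base_p
        prev = str(rng.choice(BASES, p=p))
        out.append(prev)
    return "".join(out)


def _draw_island_segment(
    rng: np.random.Generator, spec: IslandSpec, max_tries: int = 2000
) -> str:
    """Rejection-sample a segment meeting the island's GC and obs/exp targets.

    Bases are drawn i.i.d. at the target GC (which puts the expected
    obs/exp near 1), then the realized statistics are checked.
    """
    for _ in range(max_tries):
        seg = _draw_segment(rng, spec.length, spec.gc)
        if gc_fraction(seg) >= spec.gc and obs_exp_cpg(seg) >= spec.obs_exp:
            return seg
    raise FeasibilityError(
        f"island spec {spec} unsatisfied after {max_tries} draws"
    )


def generate_reference(
    params: SimulationParams, seed: int | None = None
) -> tuple[ReferenceLocus, SyntheticTruth]:
    """Draw the reference locus: background, islands, then stamped motifs.

    Motif letters take precedence over background (degenerate codes are
    resolved uniformly). Returns the locus plus a truth record whose
    per-tissue profiles are still empty (filled by
    :func:`generate_methylome` / :func:`simulate_experiment`).
    """
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    seq = list(
        _draw_background(
            rng,
            params.locus_length,
            params.background_gc,
            params.background_cpg_depletion,
        )
    )
    islands = []
    for spec in sorted(params.island_specs, key=lambda s: s.start):
        seg = _draw_island_segment(rng, spec)
        seq[spec.start : spec.start + spec.length] = seg
        islands.append(Interval(spec.start, spec.start + spec.length))
    for pm in params.planted_motifs:
        concrete = "".join(
            rng.choice(sorted(IUPAC_EXPANSION[code])) for code in pm.motif.pattern
        )
        if pm.strand == "-":
            from .seq_core import revcomp

            concrete = revcomp(concrete)
        seq[pm.start : pm.start + len(concrete)] = concrete
    locus = ReferenceLocus(
        id=f"synthetic_locus_seed{seed}",
        sequence="".join(seq),
        source=f"synthetic locus_length={params.locus_length} seed={seed}",
    )
    truth = SyntheticTruth(
        locus=locus,
        profiles={},
        planted_islands=tuple(islands),
        planted_motifs=params.planted_motifs,
        params=params,
    )
    return locus, truth


def generate_methylome(
    locus: ReferenceLocus,
    rates: Mapping[str, float],
    tissue: str,
    seed: int,
) -> MethylationProfile:
    """Independent per-cytosine Bernoulli methylation at context-specific rates.

    Context-ambiguous cytosines (locus edge, adjacent N) are never
    methylated: they are also never counted as potential sites downstream.
    """
    rng = np.random.default_rng(seed)
    states: dict[int, bool] = {}
    for pos, base in enumerate(locus.sequence):
        if base != "C":
            continue
        ctx = classify_context(locus, pos)
        if ctx is None:
            states[pos] = False
            continue
        states[pos] = bool(rng.random() < rates.get(ctx, 0.0))
    return MethylationProfile(locus_id=locus.id, states=states)


def simulate_clones(
    locus: ReferenceLocus,
    amplicon: Amplicon,
    profile: MethylationProfile,
    n_clones: int,
    efficiency: float,
    error_rate: float,
    seed: int,
    sample: str = "sample",
) -> list[CloneRead]:
    """Simulate cloned Sanger reads of one amplicon.

    Each clone is an independent bisulfite conversion of the amplicon
    region (methylated Cs protected, unmethylated Cs converted with
    probability ``efficiency``) followed by independent per-base
    substitution errors at ``error_rate`` (uniform over the three other
    bases). Reads are full-length.
    """
    rng = np.random.default_rng(seed)
    region = ReferenceLocus(
        id=locus.id,
        sequence=locus.sequence[amplicon.interval.start : amplicon.interval.end],
        source="amplicon region",
    )
    offset = amplicon.interval.start
    shifted = MethylationProfile(
        locus_id=locus.id,
        states={
            pos - offset: m
            for pos, m in profile.states.items()
            if amplicon.interval.contains(pos)
        },
    )
    reads = []
    for i in range(n_clones):
        converted = list(convert_bisulfite(region, shifted, efficiency, rng))
        if error_rate > 0:
            errs = np.nonzero(rng.random(len(converted)) < error_rate)[0]
            for j in errs:
                alternatives = [b for b in "ACGT" if b != converted[j]]
                converted[j] = alternatives[rng.integers(3)]
        reads.append(
            CloneRead(
                clone_id=f"{sample}_clone{i + 1:02d}",
                sample=sample,
                sequence="".join(converted),
            )
        )
    return reads


def design_primer_pair(
    locus: ReferenceLocus,
    product_start: int,
    product_end: int,
    primer_len: int = 24,
    gene: str = "synthetic",
) -> BisulfitePrimerPair:
    """Derive a primer pair from the fully converted top strand.

    The forward primer is the converted substring at ``product_start``;
    the reverse primer is the reverse complement of the converted
    substring ending at ``product_end``. Because the template is the
    all-unmethylated conversion, the primers are concrete (no degenerate
    codes needed).
    """
    conv = fully_converted_top(locus)
    fwd = conv[product_start : product_start + primer_len]
    rev_region = conv[product_end - primer_len : product_end]
    from .seq_core import revcomp

    return BisulfitePrimerPair(
        gene=gene,
        forward=fwd,
        reverse=revcomp(rev_region),
        expected_product_bp=product_end - product_start,
    )


def design_assay(
    locus: ReferenceLocus,
    truth: SyntheticTruth,
    half_width: int = 200,
) -> Amplicon:
    """Place a specific primer pair around the first planted island.

    Falls back to the locus middle when no island was planted; primer
    length grows until the pair is unique on the converted template.
    """
    if truth.planted_islands:
        centre = (truth.planted_islands[0].start + truth.planted_islands[0].end) // 2
    else:
        centre = len(locus) // 2
    start = max(0, centre - half_width)
    end = min(len(locus), centre + half_width)
    for primer_len in (24, 30, 36):
        pair = design_primer_pair(locus, start, end, primer_len, gene=locus.id)
        try:
            return in_silico_pcr(pair, locus)
        except NonSpecificPrimerError:
            continue
    raise FeasibilityError("could not place a specific primer pair")


def simulate_dataset(params: SimulationParams, outdir, seed: int | None = None):
    """Write a complete runnable dataset: reference, clones, primers, truth.

    Produces ``reference.fa``, ``clones.fa`` (all tissues, with
    ``sample=<tissue> gene=<locus>`` description keys), ``primers.tsv``,
    ``truth.tsv`` (position, context, tissue, state) and ``params.yaml``
    under ``outdir``, and returns the populated :class:`SyntheticTruth`.
    """
    import yaml
    from pathlib import Path

    from .seq_core import write_fasta

    seed = params.seed if seed is None else seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    locus, truth = generate_reference(params, seed)
    amplicon = design_assay(locus, truth)

    profiles: dict[str, MethylationProfile] = {}
    clone_records = []
    for t_idx, (tissue, rates) in enumerate(sorted(params.methylation_rates.items())):
        profile = generate_methylome(locus, rates, tissue, _derive_seed(seed, 1, t_idx))
        profiles[tissue] = profile
        for read in simulate_clones(
            locus, amplicon, profile, params.n_clones,
            params.conversion_efficiency, params.sequencing_error,
            _derive_seed(seed, 2, t_idx), sample=tissue,
        ):
            clone_records.append(
                ReferenceLocus(
                    id=read.clone_id,
                    sequence=read.sequence,
                    source=f"sample={tissue} gene={locus.id}",
                )
            )
    write_fasta(outdir / "reference.fa", [locus])
    write_fasta(outdir / "clones.fa", clone_records)

    pair = amplicon.primer_pair
    with open(outdir / "primers.tsv", "w") as fh:
        fh.write("gene\tforward\treverse\texpected_bp\tannealing_c\n")
        fh.write(
            f"{pair.gene}\t{pair.forward}\t{pair.reverse}\t{pair.expected_product_bp}\t50\n"
        )
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("locus\tposition\tcontext\ttissue\tstate\n")
        for tissue, profile in sorted(profiles.items()):
            for pos in sorted(profile.states):
                ctx = classify_context(locus, pos) or "ambiguous"
                state = "methylated" if profile.states[pos] else "unmethylated"
                fh.write(f"{locus.id}\t{pos}\t{ctx}\t{tissue}\t{state}\n")
    with open(outdir / "params.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "locus_length": params.locus_length,
                "background_gc": params.background_gc,
                "n_clones": params.n_clones,
                "conversion_efficiency": params.conversion_efficiency,
                "sequencing_error": params.sequencing_error,
                "methylation_rates": {
                    t: dict(r) for t, r in params.methylation_rates.items()
                },
                "seed": seed,
                "amplicon": [amplicon.interval.start, amplicon.interval.end],
            },
            fh,
            sort_keys=True,
        )
    return SyntheticTruth(
        locus=locus,
        profiles=profiles,
        planted_islands=truth.planted_islands,
        planted_motifs=truth.planted_motifs,
        params=params,
    )


def _derive_seed(base: int, *salts: int) -> int:
    """Stable small sub-seed derived from a base seed (kept below 2**31)."""
    ss = np.random.SeedSequence(entropy=base, spawn_key=tuple(salts))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class RecoveryReport:
    """Truth-vs-called comparison from :func:`recovery_experiment`.

    Sensitivity/specificity are per (site, clone) pair over callable
    positions; ``any_clone`` / ``all_clone`` aggregate to site level.
    ``denominators_match`` checks that the pipeline's potential-site
    counts equal direct enumeration of the truth locus.
    """

    per_tissue: Mapping[str, Mapping[str, float]]
    denominators_match: bool
    truth_sites: Mapping[str, Mapping[str, int]]
    #: tissue -> context -> (methylated calls, total calls) over
    #: (truth-methylated site, accepted clone) pairs
    clone_level: Mapping[str, Mapping[str, tuple[int, int]]]


def recovery_experiment(params: SimulationParams, seed: int | None = None) -> RecoveryReport:
    """Run the whole chain on simulated data and score calls against truth.

    Generates a locus, designs a primer pair around the first island
    (product ~400 bp), simulates per-tissue clone sets, then runs
    in-silico PCR, alignment and calling, and compares per-site calls to
    the generating methylome.
    """
    from .bisulfite import (
        CloneRejectedError,
        align_clone,
        call_methylation,
        callable_positions,
        count_potential_sites,
    )

    seed = params.seed if seed is None else seed
    locus, truth = generate_reference(params, seed)
    # amplicon around the first planted island (or locus middle if none)
    if truth.planted_islands:
        centre = (truth.planted_islands[0].start + truth.planted_islands[0].end) // 2
    else:
        centre = len(locus) // 2
    half = 200
    start = max(0, centre - half)
    end = min(len(locus), centre + half)
    # longer primers resolve rare incidental second matches on the converted template
    for primer_len in (24, 30, 36):
        pair = design_primer_pair(locus, start, end, primer_len, gene="synthetic")
        try:
            amplicon = in_silico_pcr(pair, locus)
            break
        except NonSpecificPrimerError:
            continue
    else:
        raise FeasibilityError("could not place a specific primer pair")

    counts = count_potential_sites(locus, [amplicon])
    callable_ = callable_positions(locus, amplicon)
    enum_counts = {"CpG": 0, "CpHpG": 0, "CpHpH": 0}
    for _, ctx in callable_:
        enum_counts[ctx] += 1
    denominators_match = counts.by_context() == enum_counts

    per_tissue: dict[str, dict[str, float]] = {}
    truth_sites: dict[str, dict[str, int]] = {}
    clone_level: dict[str, dict[str, tuple[int, int]]] = {}
    for t_idx, (tissue, rates) in enumerate(sorted(params.methylation_rates.items())):
        profile = generate_methylome(
            locus, rates, tissue, _derive_seed(seed, 1, t_idx)
        )
        reads = simulate_clones(
            locus,
            amplicon,
            profile,
            params.n_clones,
            params.conversion_efficiency,
            params.sequencing_error,
            _derive_seed(seed, 2, t_idx),
            sample=tissue,
        )
        calls = []
        for read in reads:
            try:
                aln = align_clone(read, locus, amplicon)
            except CloneRejectedError:
                # heavily corrupted clones drop out, as in the real assay
                continue
            calls.extend(call_methylation(aln, locus))

        truth_meth = {
            pos for pos, _ in callable_ if profile.is_methylated(pos)
        }
        truth_sites[tissue] = {
            ctx: sum(1 for pos, c in callable_ if c == ctx and pos in truth_meth)
            for ctx in enum_counts
        }
        tp = fn = tn = fp = 0
        site_detected: dict[int, int] = {}
        ctx_counts = {ctx: [0, 0] for ctx in enum_counts}
        for c in calls:
            truly = c.ref_pos in truth_meth
            if truly:
                ctx_counts[c.context][1] += 1
                if c.status == "methylated":
                    ctx_counts[c.context][0] += 1
            if c.status == "methylated":
                site_detected[c.ref_pos] = site_detected.get(c.ref_pos, 0) + 1
                tp += truly
                fp += not truly
            elif c.status == "unmethylated":
                fn += truly
                tn += not truly
            else:  # uncallable counts as a miss for the methylated class
                fn += truly
        n_meth = len(truth_meth)
        n_unmeth = len(callable_) - n_meth
        any_clone = (
            sum(1 for p in truth_meth if site_detected.get(p, 0) >= 1) / n_meth
            if n_meth
            else 1.0
        )
        all_clone = (
            sum(1 for p in truth_meth if site_detected.get(p, 0) == params.n_clones)
            / n_meth
            if n_meth
            else 1.0
        )
        per_tissue[tissue] = {
            "sensitivity": tp / (tp + fn) if (tp + fn) else 1.0,
            "specificity": tn / (tn + fp) if (tn + fp) else 1.0,
            "any_clone_recovery": any_clone,
            "all_clone_recovery": all_clone,
            "n_truth_methylated": float(n_meth),
            "n_truth_unmethylated": float(n_unmeth),
        }
        clone_level[tissue] = {
            ctx: (detected, trials) for ctx, (detected, trials) in ctx_counts.items()
        }
    return RecoveryReport(
        per_tissue=per_tissue,
        denominators_match=denominators_match,
        truth_sites=truth_sites,
        clone_level=clone_level,
    )
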