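"""End-to-end orchestration and report rendering.

``run_pipeline`` chains island prediction, in-silico PCR, clone
alignment and calling, clone summaries, and motif methylation status
over plain-text inputs (reference FASTA, clone FASTA, primer TSV, motif
TSV) and writes tab-separated reports plus BED tracks into a run
directory. Outputs are a pure function of (inputs, config): re-running
the same configuration reproduces them byte for byte.

Clone FASTA records associate to genes and tissues through
``sample=<tissue> gene=<locus-id>`` keys in the description line; each
clone is assigned to the amplicon of its gene whose length is closest
to the read length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bisulfite import (
    Amplicon,
    CloneRead,
    CloneRejectedError,
    MethylationCall,
    align_clone,
    call_methylation,
    callable_positions,
    count_potential_sites,
    in_silico_pcr,
    read_primer_table,
    summarize_clones,
)
from .cpg_islands import CpGIsland, IslandParams, find_cpg_islands, islands_to_bed
from .motifs import (
    MotifInstance,
    default_catalog,
    load_motif_table,
    motif_methylation_status,
    scan_motifs,
    status_to_frame,
)
from .seq_core import BedRecord, ReferenceLocus, read_fasta, write_bed

logger = logging.getLogger(__name__)

CONTEXTS = ("CpG", "CpHpG", "CpHpH")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and echoes its input."""


@dataclass
class RunConfig:
    reference_fasta: str
    clones_fasta: str
    primer_tsv: str
    output_dir: str
    motif_tsv: str | None = None  # None -> shipped catalogue
    island_params: IslandParams = field(default_factory=IslandParams)
    min_identity: float = 0.90
    max_primer_mismatch: int = 0
    min_clones: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        island = IslandParams(**raw.pop("island_params", {}))
        return cls(island_params=island, **raw)

    def to_dict(self) -> dict:
        d = {
            "reference_fasta": self.reference_fasta,
            "clones_fasta": self.clones_fasta,
            "primer_tsv": self.primer_tsv,
            "motif_tsv": self.motif_tsv,
            "output_dir": self.output_dir,
            "island_params": vars(self.island_params),
            "min_identity": self.min_identity,
            "max_primer_mismatch": self.max_primer_mismatch,
            "min_clones": self.min_clones,
            "seed": self.seed,
        }
        return d


def parse_clone_fasta(path: str | Path) -> list[CloneRead]:
    """Clone reads with sample/gene parsed from ``key=value`` description fields."""
    reads = []
    for locus in read_fasta(path):
        fields = dict(
            kv.split("=", 1) for kv in locus.source.split() if "=" in kv
        )
        reads.append(
            CloneRead(
                clone_id=locus.id,
                sample=fields.get("sample", "sample"),
                sequence=locus.sequence,
            )
        )
    return reads


def _clone_gene_map(path: str | Path) -> dict[str, str]:
    return {
        locus.id: dict(
            kv.split("=", 1) for kv in locus.source.split() if "=" in kv
        ).get("gene", "")
        for locus in read_fasta(path)
    }


def render_track(
    calls: list[MethylationCall],
    islands: list[CpGIsland],
    instances: list[MotifInstance],
    locus: ReferenceLocus,
) -> tuple[list[BedRecord], str]:
    """Per-site track: BED records plus a text lollipop rendering.

    One BED record per potential site; the name field packs
    ``context|predicted|detected_cpg|detected_noncpg`` (predicted = the
    site lies in a predicted island) and the score is the maximum clone
    support across samples. The text rendering prints, per sample, one
    glyph per site: ``#`` methylated CpG, ``o`` methylated non-CpG
    (the "non-canonical" marks), ``.`` unmethylated.
    """
    sites = sorted({(c.ref_pos, c.context) for c in calls})
    samples = sorted({c.sample for c in calls})
    support: dict[tuple[int, str], set[str]] = {}
    for c in calls:
        if c.status == "methylated":
            support.setdefault((c.ref_pos, c.sample), set()).add(c.clone_id)
    total_clones = {
        s: len({c.clone_id for c in calls if c.sample == s}) for s in samples
    }

    records = []
    for pos, ctx in sites:
        predicted = any(isl.interval.contains(pos) for isl in islands)
        best = max(
            (len(support.get((pos, s), ())) for s in samples), default=0
        )
        detected_cpg = ctx == "CpG" and best > 0
        detected_noncpg = ctx != "CpG" and best > 0
        records.append(
            BedRecord(
                chrom=locus.id,
                start=pos,
                end=pos + 1,
                name=f"{ctx}|predicted={int(predicted)}|cpg={int(detected_cpg)}|noncpg={int(detected_noncpg)}",
                score=str(best),
            )
        )

    lines = [f"# locus {locus.id}: {len(sites)} potential sites (left to right)"]
    island_line = "".join(
        "^" if any(isl.interval.contains(pos) for isl in islands) else " "
        for pos, _ in sites
    )
    lines.append(f"{'island':>12} {island_line}")
    for s in samples:
        glyphs = []
        for pos, ctx in sites:
            n = len(support.get((pos, s), ()))
            if n == 0:
                glyphs.append(".")
            elif ctx == "CpG":
                glyphs.append("#")
            else:
                glyphs.append("o")
        lines.append(f"{s:>12} {''.join(glyphs)} ({total_clones.get(s, 0)} clones)")
    return records, "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full chain and write all reports into the run directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name: str, detail: str = ""):
        logger.info("stage %s %s", name, detail)

    try:
        stage("read_reference", config.reference_fasta)
        loci = {l.id: l for l in read_fasta(config.reference_fasta)}
    except Exception as exc:
        raise PipelineError(f"read_reference({config.reference_fasta}): {exc}") from exc

    # --- islands -----------------------------------------------------------
    islands_by_locus: dict[str, list[CpGIsland]] = {}
    bed_records = []
    for locus in loci.values():
        islands_by_locus[locus.id] = find_cpg_islands(locus, config.island_params)
        bed_records.extend(islands_to_bed(locus, islands_by_locus[locus.id]))
    write_bed(outdir / "islands.bed", bed_records)

    # --- PCR ---------------------------------------------------------------
    try:
        pairs = read_primer_table(config.primer_tsv)
    except Exception as exc:
        raise PipelineError(f"read_primers({config.primer_tsv}): {exc}") from exc
    amplicons_by_gene: dict[str, list[Amplicon]] = {}
    for pair in pairs:
        if pair.gene not in loci:
            raise PipelineError(f"pcr: primer gene {pair.gene!r} has no reference locus")
        try:
            amp = in_silico_pcr(pair, loci[pair.gene], config.max_primer_mismatch)
        except Exception as exc:
            raise PipelineError(f"pcr({pair.gene}): {exc}") from exc
        amplicons_by_gene.setdefault(pair.gene, []).append(amp)

    # --- clones: align and call -------------------------------------------
    try:
        clones = parse_clone_fasta(config.clones_fasta)
        gene_of = _clone_gene_map(config.clones_fasta)
    except Exception as exc:
        raise PipelineError(f"read_clones({config.clones_fasta}): {exc}") from exc

    calls_by_gene_sample: dict[tuple[str, str], list[MethylationCall]] = {}
    rejected = []
    for read in clones:
        gene = gene_of.get(read.clone_id, "")
        if gene not in amplicons_by_gene:
            raise PipelineError(f"call: clone {read.clone_id} names unknown gene {gene!r}")
        amps = amplicons_by_gene[gene]
        amp = min(amps, key=lambda a: abs(a.length - len(read.sequence)))
        try:
            aln = align_clone(read, loci[gene], amp, config.min_identity)
        except CloneRejectedError as exc:
            logger.warning("%s", exc)
            rejected.append(read.clone_id)
            continue
        calls_by_gene_sample.setdefault((gene, read.sample), []).extend(
            call_methylation(aln, loci[gene])
        )

    all_calls = [c for calls in calls_by_gene_sample.values() for c in calls]
    calls_df = pd.DataFrame(
        [
            {
                "locus": gene,
                "position": c.ref_pos,
                "context": c.context,
                "status": c.status,
                "clone_id": c.clone_id,
                "sample": c.sample,
            }
            for (gene, _), calls in sorted(calls_by_gene_sample.items())
            for c in sorted(calls, key=lambda c: (c.ref_pos, c.clone_id))
        ]
    )
    calls_df.to_csv(outdir / "calls.tsv", sep="\t", index=False)

    # --- summaries ---------------------------------------------------------
    wide_rows = []
    long_rows = []
    for (gene, sample), calls in sorted(calls_by_gene_sample.items()):
        denoms = count_potential_sites(loci[gene], amplicons_by_gene[gene])
        n_clones = len({c.clone_id for c in calls})
        summary = summarize_clones(calls, denoms, n_clones, gene=gene, sample=sample)
        row = {"gene": gene, "sample": sample, "n_clones": n_clones}
        for ctx in CONTEXTS:
            row[ctx] = summary.format_cell(ctx)
        wide_rows.append(row)
        for ctx in CONTEXTS:
            for k, m in summary.groups[ctx]:
                long_rows.append(
                    {
                        "gene": gene,
                        "sample": sample,
                        "context": ctx,
                        "k_methylated": k,
                        "denominator": summary.denominators.by_context()[ctx],
                        "m_clones": m,
                        "n_clones": n_clones,
                    }
                )
    pd.DataFrame(wide_rows).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    pd.DataFrame(long_rows).to_csv(outdir / "summary_long.tsv", sep="\t", index=False)

    # --- motifs ------------------------------------------------------------
    motifs = (
        load_motif_table(config.motif_tsv) if config.motif_tsv else default_catalog()
    )
    status_frames = []
    track_beds = []
    track_texts = []
    for gene in sorted(amplicons_by_gene):
        locus = loci[gene]
        instances = scan_motifs(locus, motifs, strands="both")
        calls_by_sample = {
            sample: calls
            for (g, sample), calls in sorted(calls_by_gene_sample.items())
            if g == gene
        }
        statuses = motif_methylation_status(
            instances, calls_by_sample, config.min_clones
        )
        status_frames.append(status_to_frame(statuses))
        gene_calls = [c for calls in calls_by_sample.values() for c in calls]
        beds, text = render_track(
            gene_calls, islands_by_locus[gene], instances, locus
        )
        track_beds.extend(beds)
        track_texts.append(text)
    if status_frames:
        pd.concat(status_frames, ignore_index=True).to_csv(
            outdir / "motif_status.tsv", sep="\t", index=False
        )
    write_bed(outdir / "track.bed", track_beds)
    (outdir / "track.txt").write_text("\n".join(track_texts))

    # --- run log -----------------------------------------------------------
    log = {
        "methclone_version": __version__,
        "config": config.to_dict(),
        "n_loci": len(loci),
        "n_primer_pairs": len(pairs),
        "n_clones": len(clones),
        "rejected_clones": rejected,
        "islands": {
            lid: [[isl.interval.start, isl.interval.end] for isl in isls]
            for lid, isls in sorted(islands_by_locus.items())
        },
    }
    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    return outdir
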