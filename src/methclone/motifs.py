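"""IUPAC scanning of cis-regulatory elements and their methylation status.

The catalogue mirrors the PLACE-style motif dictionary (name, degenerate
IUPAC pattern, function, PLACE identifier). Scanning is exact degenerate
string matching on both strands by default; a minus-strand hit is a
window whose reverse complement matches the pattern. Each motif instance
is then annotated per tissue: "+" when at least ``min_clones`` clones
carry a methylated cytosine (any context — CpG, CpHpG or CpHpH) inside
the instance interval, "-" otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .bisulfite import MethylationCall
from .seq_core import (
    IUPAC_EXPANSION,
    BedRecord,
    Interval,
    ReferenceLocus,
    iupac_match,
    revcomp,
)

logger = logging.getLogger(__name__)


class MotifTableError(ValueError):
    """The motif catalogue TSV is malformed."""


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    pattern: str
    function: str = ""
    place_id: str = ""

    def __post_init__(self) -> None:
        if len(self.pattern) < 3:
            raise MotifTableError(f"{self.name}: pattern shorter than 3 nt")
        bad = set(self.pattern.upper()) - set(IUPAC_EXPANSION)
        if bad:
            raise MotifTableError(
                f"{self.name}: invalid IUPAC characters {sorted(bad)}"
            )
        object.__setattr__(self, "pattern", self.pattern.upper())


@dataclass(frozen=True)
class MotifInstance:
    motif: MotifDefinition
    locus_id: str
    interval: Interval

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class MotifMethylationStatus:
    instance: MotifInstance
    sample: str
    status: str  # "+" or "-"
    supporting_clones: int


def load_motif_table(path: str | Path) -> list[MotifDefinition]:
    """Load a 4-column TSV catalogue (name, pattern, function, place_id).

    Rows duplicated by (name, pattern) are rejected; an empty file yields
    an empty list with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"name", "pattern", "function", "place_id"}
    missing = required - set(df.columns)
    if missing:
        raise MotifTableError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        logger.warning("%s: empty motif table", path)
        return []
    motifs = []
    seen = set()
    for idx, row in df.iterrows():
        try:
            m = MotifDefinition(
                name=row["name"],
                pattern=row["pattern"],
                function=row["function"],
                place_id=row["place_id"],
            )
        except MotifTableError as exc:
            raise MotifTableError(f"{path}: row {idx + 2}: {exc}") from exc
        key = (m.name, m.pattern)
        if key in seen:
            raise MotifTableError(f"{path}: row {idx + 2}: duplicate {key}")
        seen.add(key)
        motifs.append(m)
    return motifs


def default_catalog() -> list[MotifDefinition]:
    """The shipped promoter-element catalogue (PLACE-style, deduplicated)."""
    ref = resources.files("methclone.data") / "motif_catalog.tsv"
    with resources.as_file(ref) as path:
        return load_motif_table(path)


def scan_motifs(
    locus: ReferenceLocus,
    motifs: Sequence[MotifDefinition],
    strands: str = "both",
) -> list[MotifInstance]:
    """All degenerate matches of every motif on the requested strands.

    Overlapping instances of the same motif are all reported; output is
    sorted by start, then motif name, then strand.
    """
    if strands not in {"+", "-", "both"}:
        raise ValueError(f"strands must be +, - or both, got {strands!r}")
    seq = locus.sequence
    hits = []
    for motif in motifs:
        L = len(motif.pattern)
        rc_pattern = revcomp(motif.pattern)
        for i in range(len(seq) - L + 1):
            window = seq[i : i + L]
            if strands in {"+", "both"} and iupac_match(motif.pattern, window):
                hits.append(
                    MotifInstance(motif, locus.id, Interval(i, i + L, "+"))
                )
            if strands in {"-", "both"} and iupac_match(rc_pattern, window):
                hits.append(
                    MotifInstance(motif, locus.id, Interval(i, i + L, "-"))
                )
    hits.sort(key=lambda h: (h.interval.start, h.motif.name, h.interval.strand))
    return hits


def motif_methylation_status(
    instances: Sequence[MotifInstance],
    calls_by_sample: Mapping[str, Iterable[MethylationCall]],
    min_clones: int = 1,
) -> list[MotifMethylationStatus]:
    """Annotate each instance x sample with its methylation status.

    "+" iff some cytosine inside the instance interval is methylated in at
    least ``min_clones`` distinct clones of that sample (any sequence
    context); the supporting clone count is the maximum over positions.
    """
    out = []
    for sample, calls in calls_by_sample.items():
        support: dict[int, set[str]] = {}
        for c in calls:
            if c.status == "methylated":
                support.setdefault(c.ref_pos, set()).add(c.clone_id)
        for inst in instances:
            best = 0
            for pos, clones in support.items():
                if inst.interval.contains(pos):
                    best = max(best, len(clones))
            status = "+" if best >= min_clones else "-"
            out.append(
                MotifMethylationStatus(
                    instance=inst,
                    sample=sample,
                    status=status,
                    supporting_clones=best,
                )
            )
    return out


def instances_to_bed(instances: Sequence[MotifInstance]) -> list[BedRecord]:
    return [
        BedRecord(
            chrom=inst.locus_id,
            start=inst.interval.start,
            end=inst.interval.end,
            name=inst.motif.name,
            score="0",
            strand=inst.interval.strand,
        )
        for inst in instances
    ]


def status_to_frame(statuses: Sequence[MotifMethylationStatus]) -> pd.DataFrame:
    """Wide per-instance table: one row per instance, one +/- column per sample."""
    rows = {}
    samples = []
    for st in statuses:
        if st.sample not in samples:
            samples.append(st.sample)
        inst = st.instance
        key = (inst.locus_id, inst.interval.start, inst.interval.end,
               inst.interval.strand, inst.motif.name)
        row = rows.setdefault(
            key,
            {
                "locus": inst.locus_id,
                "motif": inst.motif.name,
                "pattern": inst.motif.pattern,
                "place_id": inst.motif.place_id,
                "start": inst.interval.start,
                "end": inst.interval.end,
                "strand": inst.interval.strand,
            },
        )
        row[f"status_{st.sample}"] = st.status
        row[f"clones_{st.sample}"] = st.supporting_clones
    df = pd.DataFrame(list(rows.values()))
    if not df.empty:
        df = df.sort_values(["locus", "start", "motif", "strand"]).reset_index(drop=True)
    return df
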