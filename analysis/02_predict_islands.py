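"""Predict CpG islands on the simulated reference.

Slides the classical 100 bp window (GC >= 0.50, CpG obs/exp >= 0.60)
over the locus, writes the ordinally numbered islands to
results/islands.bed, and reports whether each planted island was
recovered.
"""

from pathlib import Path

import yaml

from methclone.cpg_islands import find_cpg_islands, islands_to_bed
from methclone.seq_core import Interval, read_fasta, write_bed

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    locus = read_fasta(ROOT / "dataset" / "reference.fa")[0]
    params_echo = yaml.safe_load((ROOT / "dataset" / "params.yaml").read_text())
    islands = find_cpg_islands(locus)
    write_bed(ROOT / "islands.bed", islands_to_bed(locus, islands))
    print(f"{locus.id}: {len(islands)} island(s)")
    for isl in islands:
        print(
            f"  {isl.name}: [{isl.interval.start}, {isl.interval.end}) "
            f"{len(isl.interval)} bp, gc={isl.gc:.3f}, obs/exp={isl.obs_exp:.3f}"
        )
    amp_start, amp_end = params_echo["amplicon"]
    amp = Interval(amp_start, amp_end)
    overlapping = [isl.name for isl in islands if isl.interval.overlaps(amp)]
    print(f"amplicon [{amp_start}, {amp_end}) overlaps: {overlapping or 'none'}")


if __name__ == "__main__":
    main()
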