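"""Overlap methylation marks with cis-regulatory elements.

Scans the reference for the shipped PLACE-style catalogue on both
strands and marks each instance +/- per tissue from the clone calls
(+ means methylated in at least one clone inside the element). Writes
results/motif_status_summary.tsv and prints the differentially
methylated elements.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    status = pd.read_csv(ROOT / "run" / "motif_status.tsv", sep="\t")
    n_inst = len(status)
    plus_cols = [c for c in status.columns if c.startswith("status_")]
    print(f"{n_inst} motif instances scanned; per-tissue methylated counts:")
    for col in plus_cols:
        print(f"  {col.removeprefix('status_')}: {(status[col] == '+').sum()} of {n_inst}")
    diff = status[status[plus_cols].nunique(axis=1) > 1] if len(plus_cols) > 1 else status.iloc[0:0]
    summary = (
        status.groupby(["motif", "pattern", "place_id"])[plus_cols]
        .agg(lambda s: (s == "+").sum())
        .reset_index()
    )
    summary.to_csv(ROOT / "motif_status_summary.tsv", sep="\t", index=False)
    print(f"\n{len(diff)} instances differ between tissues; examples:")
    if not diff.empty:
        print(diff.head(10).to_string(index=False))
    print(f"\nper-motif summary written to {ROOT / 'motif_status_summary.tsv'}")


if __name__ == "__main__":
    main()
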