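"""Generate the synthetic study dataset.

Draws a ~1.6 kb promoter-like locus with two planted CpG islands,
per-tissue methylomes (coleoptile unmethylated, root weakly methylated
at CpG > CpHpG > CpHpH rates), and 10 bisulfite clone reads per tissue
for one ~400 bp amplicon, then writes the dataset under
results/dataset/ (reference.fa, clones.fa, primers.tsv, truth.tsv,
params.yaml).
"""

from pathlib import Path

from methclone.synthetic import SimulationParams, simulate_dataset

SEED = 20220511
OUT = Path(__file__).resolve().parent.parent / "results" / "dataset"


def main() -> None:
    params = SimulationParams(seed=SEED)
    truth = simulate_dataset(params, OUT, SEED)
    n_meth = {
        tissue: len(profile.methylated_positions)
        for tissue, profile in sorted(truth.profiles.items())
    }
    print(f"locus {truth.locus.id}: {len(truth.locus)} bp")
    print(f"planted islands: {[(i.start, i.end) for i in truth.planted_islands]}")
    print(f"truth methylated cytosines per tissue: {n_meth}")
    print(f"dataset written to {OUT}")


if __name__ == "__main__":
    main()
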