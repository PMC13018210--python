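#!/usr/bin/env python
"""Generate the fixed planted-genome benchmark (seed 1337).

20 genomes x 200 kb with 30 true three-domain cassettes, 30 decoys (10 each
of shuffled order, strand-split, partial), and immunity-like ORFs planted
downstream of cassettes.  Genomes (several MB) go to scratch/; the truth
table and a per-kind tally go to results/.
"""

from pathlib import Path

from tlpscan import seqio, synthetic_data
from tlpscan.profile_hmm import read_library

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    lib = read_library(SCRATCH / "superfold.hmmlib")
    cfg = synthetic_data.GeneratorConfig()
    genomes, metadata, truth = synthetic_data.generate_benchmark(cfg, lib)
    out = SCRATCH / "benchmark"
    out.mkdir(exist_ok=True)
    seqio.write_fasta(genomes, out / "genomes.fasta")
    seqio.write_metadata(metadata, out / "metadata.tsv")
    synthetic_data.write_truth(truth, RESULTS / "benchmark_truth.tsv")
    df = synthetic_data.truth_to_dataframe(truth)
    print(df["kind"].value_counts().to_string())
    print(f"\ngenomes -> {out / 'genomes.fasta'}")
    print(f"truth   -> {RESULTS / 'benchmark_truth.tsv'}")


if __name__ == "__main__":
    main()
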