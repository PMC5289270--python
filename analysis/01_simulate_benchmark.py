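"""Generate the synthetic study world: dimer library, candidate pairs,
interaction network and annotation tables.

Writes the benchmark truth table, the native network edge list and the
per-protein annotations under results/; the PDB files of the library and
monomer models go to scratch/benchmark/ (they are regenerated exactly by
the seed, so only the small tables are kept with the results).
"""

from pathlib import Path

import networkx as nx

from misint.synthetic_data import (
    GeneratorConfig,
    make_annotations,
    make_benchmark,
    make_network,
    write_benchmark,
)

SEED = 11
N_TEMPLATES, N_POS, N_NEG = 8, 16, 20

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "benchmark"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = GeneratorConfig(seed=SEED)
    bench = make_benchmark(N_TEMPLATES, N_POS, N_NEG, cfg)
    write_benchmark(bench, SCRATCH)
    truth = bench.truth()
    truth.to_csv(RESULTS / "benchmark_truth.tsv", sep="\t", index=False)

    net = make_network(300, 5.0, seed=SEED)
    nx.write_edgelist(net, RESULTS / "native_network.tsv", delimiter="\t", data=False)

    ann = make_annotations(sorted(net.nodes), seed=SEED)
    ann.to_csv(RESULTS / "annotations.tsv", sep="\t", index=False)

    n_pos = (truth["label"] == "interacting").sum()
    n_comp = (truth["kind"] == "negative-compatible").sum()
    print(f"library: {len(bench.library)} template dimers "
          f"(all >10 residue contacts at 5 A)")
    print(f"pairs: {n_pos} interacting, {len(truth) - n_pos} non-interacting "
          f"({n_comp} structure-compatible)")
    print(f"network: {net.number_of_nodes()} proteins, {net.number_of_edges()} edges")
    print(f"tables -> {RESULTS}, structures -> {SCRATCH}")


if __name__ == "__main__":
    main()
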