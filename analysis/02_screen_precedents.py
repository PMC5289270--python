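"""Screen every candidate pair against the dimer library.

For each (pair, template) combination both chain assignments are scored
by TM-score; hits are validated by the interface rule (>= 20 interface
residues at 5 A, fewer than three CA clashes).  Writes the full screen
table and the per-pair best valid precedents at the 0.6 threshold.
"""

from pathlib import Path

from misint.pipeline import best_hits, planted_recovery_rate, screen_benchmark
from misint.synthetic_data import GeneratorConfig, make_benchmark

SEED = 11
N_TEMPLATES, N_POS, N_NEG = 8, 16, 20

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = GeneratorConfig(seed=SEED)
    bench = make_benchmark(N_TEMPLATES, N_POS, N_NEG, cfg)
    screen = screen_benchmark(bench)
    screen.to_csv(RESULTS / "screen.tsv", sep="\t", index=False)

    best = best_hits(screen, threshold=0.6)
    best.to_csv(RESULTS / "best_hits_tm06.tsv", sep="\t", index=False)

    recovery = planted_recovery_rate(screen, threshold=0.6)
    print(f"screened {screen['pair_id'].nunique()} pairs x {N_TEMPLATES} templates")
    print(f"valid precedents at TMmin >= 0.6: {len(best)} pairs")
    print(f"planted-template recovery (positives): {100 * recovery:.1f}%")


if __name__ == "__main__":
    main()
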