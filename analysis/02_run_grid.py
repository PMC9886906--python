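"""Train the oral-condition grid and score every simulation.

Runs the 3 (oral vocabulary sizes) x 2 (exposure levels) x 2 (versions)
grid of triangle-network simulations: frequency-weighted oral training
(PS/SP/PP/SS interleaved 40/40/10/10), weight freezing, identical reading
training in every cell, evaluation on words and nonwords, and both
semantic-reliance scores per simulation.  Per-cell checkpoints make the
run resumable.  Takes roughly ten minutes on one CPU.

Run:  python analysis/02_run_grid.py [--seed N] [--out DIR]
"""

import argparse

from triread.experiment import GridSpec, run_grid


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/grid")
    ap.add_argument("--config", default=None,
                    help="GridSpec YAML overriding the default toy grid")
    args = ap.parse_args()

    grid = (GridSpec.from_yaml(args.config) if args.config else GridSpec())
    grid.master_seed = args.seed
    res = run_grid(grid, args.out, progress=True)
    cols = ["ovs", "ove", "version", "acc_op", "acc_os",
            "nonword_acc_consistent", "nonword_acc_inconsistent",
            "eoc_sr", "dol_sr"]
    print(res.sr_scores[cols].to_string(index=False))
    print(f"\nresults under {args.out}/ "
          f"(word_results.csv, sr_scores.csv, manifest.json)")


if __name__ == "__main__":
    main()
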