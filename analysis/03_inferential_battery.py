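"""The full inferential battery over a completed grid.

Reproduces the analysis chain on the simulation output: the pooled linear
mixed-effects model of phonological SSE with psycholinguistic predictors
and the likelihood-ratio test for adding the oral-knowledge variables
(OVE, OVS); the distribution and correlation of the two SR measures; the
imageability x consistency x SR factorial; the OVE x OVS interaction
regressions; and the structural path models from oral knowledge through
SR to reading performance.

Run:  python analysis/03_inferential_battery.py [--results DIR] [--out F]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from triread.experiment import GridResults, analyze, save_report


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", default="results/grid")
    ap.add_argument("--out", default="results/report.json")
    args = ap.parse_args()

    res = Path(args.results)
    results = GridResults(
        word_results=pd.read_csv(res / "word_results.csv"),
        sr_scores=pd.read_csv(res / "sr_scores.csv"))
    report = analyze(results)
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    save_report(report, args.out)

    lmm = report["lmm_reading"]
    print(f"pooled LMM ({lmm['n_obs']} observations); "
          f"LR test for OVE+OVS: chi2({lmm['lr_test']['df']}) = "
          f"{lmm['lr_test']['chi2']:.1f}, p = {lmm['lr_test']['p']:.2g}")
    coefs = pd.DataFrame(lmm["coefficients"]).T
    print(coefs[["coef", "t", "significant"]].to_string())
    print()
    for col, d in report["sr_distributions"].items():
        print(col, json.dumps(d))
    print()
    for col, d in report["sr_regressions"].items():
        print(f"{col} ~ ove * ovs: R2 = {d['r2']:.3f} "
              f"(adj {d['adj_r2']:.3f})")
    for col, d in report["structural"].items():
        print(f"structural[{col}]: CFI {d['cfi']:.3f} "
              f"RMSEA {d['rmsea']:.3f} TLI {d['tli']:.3f}")
    print(f"\nfull report -> {args.out}")


if __name__ == "__main__":
    main()
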