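"""Generate the artificial study language and its nonword test sets.

Builds the 300-word lexicon (Zipfian frequencies, 20% exception words,
3 homophone pairs, 60 semantic features) and the 80 + 80 consistent /
inconsistent nonwords, then writes them under results/language/ together
with descriptive statistics of the psycholinguistic covariates.

Run:  python analysis/01_generate_language.py [--seed N]
"""

import argparse
import json
from pathlib import Path

import numpy as np

import triread as tr
from triread.experiment import GridSpec, build_inputs


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/language")
    args = ap.parse_args()

    grid = GridSpec(master_seed=args.seed)
    lexicon, enc, nonwords = build_inputs(grid)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    lexicon.to_tsv(out / "lexicon.tsv", out / "inventory.tsv")
    with open(out / "nonwords.tsv", "w") as fh:
        fh.write("letters\tcondition\tacceptable\n")
        for nw in nonwords:
            prons = ";".join(" ".join(p)
                             for p in nw.acceptable_pronunciations)
            fh.write(f"{nw.letters}\t{nw.condition}\t{prons}\n")

    rc = np.array([it.rc for it in lexicon.items])
    stats = {
        "n_words": len(lexicon),
        "exception_fraction": float(np.mean(rc < 0.5)),
        "rc_mean": float(rc.mean()),
        "ons_mean": float(np.mean([it.ons for it in lexicon.items])),
        "img_range": [int(min(it.img for it in lexicon.items)),
                      int(max(it.img for it in lexicon.items))],
        "n_homophone_items": sum(it.context_index > 0
                                 for it in lexicon.items),
        "n_nonwords": {"consistent": sum(n.condition == "consistent"
                                         for n in nonwords),
                       "inconsistent": sum(n.condition == "inconsistent"
                                           for n in nonwords)},
    }
    (out / "language_stats.json").write_text(json.dumps(stats, indent=1))
    print("language written to", out)
    print(json.dumps(stats, indent=1))


if __name__ == "__main__":
    main()
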