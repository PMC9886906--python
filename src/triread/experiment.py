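"""Grid orchestration: language -> oral/reading training -> SR -> analysis.

One *simulation* is a cell of the oral-condition grid: an oral vocabulary
size (OVS), an oral exposure count (OVE), and a version (initial-weight
seed).  Reading training is identical across cells of a version — same
trial count and same word sequence — so that differences between cells
isolate the oral-knowledge manipulation.

Randomness is organised as named substreams derived from one master seed
(via ``numpy.random.SeedSequence``), so cells are independent and can be
computed in any order, and adding cells never perturbs existing ones.
Per-cell outputs are checkpointed as CSV/JSON and runs are resumable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import language as lang
from . import network as net
from .evaluation import evaluate_model
from .sr import dol_sr, eoc_sr
from . import stats as st

# substream tags: one per (stage); combined with cell coordinates
_STREAM_INIT, _STREAM_ORAL, _STREAM_READ, _STREAM_NONWORD = 11, 22, 33, 44


@dataclass
class GridSpec:
    """The simulation grid and everything needed to re-run it bit-identically."""

    language: lang.LanguageSpec = field(default_factory=lang.LanguageSpec)
    ovs_values: tuple[int, ...] = (100, 200, 300)
    ove_values: tuple[int, ...] = (20_000, 80_000)
    n_versions: int = 2
    reading_trials: int = 80_000
    batch_size: int = 16
    n_nonwords: int = 80          # per consistency condition
    master_seed: int = 0
    network_overrides: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.ovs_values) * len(self.ove_values) * self.n_versions

    def cells(self):
        for i, ovs in enumerate(self.ovs_values):
            for j, ove in enumerate(self.ove_values):
                for v in range(self.n_versions):
                    yield i, j, v, ovs, ove

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["language"] = asdict(self.language)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GridSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["language"] = lang.LanguageSpec(**d["language"])
        for key in ("ovs_values", "ove_values"):
            d[key] = tuple(d[key])
        return cls(**d)


def _rng(master: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master, *key]))


def build_inputs(grid: GridSpec):
    """Lexicon, encodings and the fixed nonword test sets for a grid."""
    lexicon = lang.build_language(grid.language)
    enc = lang.encode_lexicon(lexicon)
    nonwords = (
        lang.generate_nonwords(lexicon, grid.n_nonwords, "consistent",
                               _rng(grid.master_seed, _STREAM_NONWORD, 0))
        + lang.generate_nonwords(lexicon, grid.n_nonwords, "inconsistent",
                                 _rng(grid.master_seed, _STREAM_NONWORD, 1)))
    return lexicon, enc, nonwords


def run_cell(grid: GridSpec, enc: lang.EncodedLexicon,
             nonwords: list[lang.Nonword], i_ovs: int, i_ove: int,
             version: int) -> tuple[pd.DataFrame, dict]:
    """Train and evaluate one simulation; returns word results + summary."""
    ovs = grid.ovs_values[i_ovs]
    ove = grid.ove_values[i_ove]
    cfg = net.default_config(enc, **grid.network_overrides)
    params = net.init_network(cfg, _rng(grid.master_seed, _STREAM_INIT,
                                        version))
    t0 = time.perf_counter()
    net.train_oral(params, enc, net.OralCondition(ovs=ovs, ove=ove),
                   _rng(grid.master_seed, _STREAM_ORAL, i_ovs, i_ove,
                        version),
                   batch_size=grid.batch_size)
    t_oral = time.perf_counter() - t0
    params.freeze_oral()
    t0 = time.perf_counter()
    net.train_reading(params, enc, grid.reading_trials,
                      _rng(grid.master_seed, _STREAM_READ, version),
                      batch_size=grid.batch_size)
    t_read = time.perf_counter() - t0

    results, summary = evaluate_model(params, enc, nonwords)
    results["ovs"] = ovs
    results["ove"] = ove
    results["version"] = version
    # oral-task accuracy restricted to the cell's trained vocabulary
    trained = results["item_id"].isin(enc.lexicon.top_k_indices(ovs))
    acc_sp_trained = float(results.loc[trained, "sp_correct"].mean())
    acc_ps_trained = float(results.loc[trained, "ps_correct"].mean())
    score_eoc = eoc_sr(results)
    score_dol = dol_sr(params, enc)
    cell_summary = {
        "ovs": ovs, "ove": ove, "version": version,
        "eoc_sr": score_eoc.value, "eoc_sr_t": score_eoc.t,
        "dol_sr": score_dol,
        "mean_phon_sse": summary.mean_phon_sse,
        "mean_sem_sse": summary.mean_sem_sse,
        "acc_sp_trained": acc_sp_trained,
        "acc_ps_trained": acc_ps_trained,
        **{k: v for k, v in summary.to_dict().items()
           if not isinstance(v, dict)},
        **{f"nonword_acc_{k}": v for k, v in summary.nonword_acc.items()},
        "seconds_oral": round(t_oral, 2), "seconds_reading": round(t_read, 2),
    }
    return results, cell_summary


@dataclass
class GridResults:
    word_results: pd.DataFrame    # one row per word x simulation
    sr_scores: pd.DataFrame       # one row per simulation


def run_grid(grid: GridSpec, outdir: str | Path | None = None,
             progress: bool = False) -> GridResults:
    """Run every cell (resuming from per-cell checkpoints when present)."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        (out / "cells").mkdir(parents=True, exist_ok=True)
    lexicon, enc, nonwords = build_inputs(grid)

    all_words, all_scores = [], []
    for i, j, v, ovs, ove in grid.cells():
        tag = f"ovs{ovs}_ove{ove}_v{v}"
        words_path = out / "cells" / f"{tag}_words.csv" if out else None
        summ_path = out / "cells" / f"{tag}_summary.json" if out else None
        if words_path is not None and words_path.exists() \
                and summ_path.exists():
            results = pd.read_csv(words_path)
            cell_summary = json.loads(summ_path.read_text())
        else:
            if progress:
                print(f"[triread] running cell {tag}", flush=True)
            results, cell_summary = run_cell(grid, enc, nonwords, i, j, v)
            if words_path is not None:
                results.to_csv(words_path, index=False)
                summ_path.write_text(json.dumps(cell_summary, indent=1))
        all_words.append(results)
        all_scores.append(cell_summary)

    word_results = pd.concat(all_words, ignore_index=True)
    sr_scores = pd.DataFrame(all_scores)
    if out is not None:
        word_results.to_csv(out / "word_results.csv", index=False)
        sr_scores.to_csv(out / "sr_scores.csv", index=False)
        manifest = {
            "config_hash": grid.config_hash(),
            "master_seed": grid.master_seed,
            "n_cells": grid.n_cells,
            "grid": json.loads(json.dumps(asdict(grid), default=str)),
            "outputs": ["word_results.csv", "sr_scores.csv", "cells/"],
            "dol_probe_set": "full lexicon",
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return GridResults(word_results=word_results, sr_scores=sr_scores)


# --------------------------------------------------------------------------
# analysis over a completed grid
# --------------------------------------------------------------------------

def _factorial_table(word_results: pd.DataFrame, sr_scores: pd.DataFrame,
                     sr_col: str) -> tuple[st.ModelFit, pd.DataFrame]:
    """Imageability x consistency x SR LMM on factorial item subsets.

    Consistent items are those from fully consistent rime families
    (rc = 1); inconsistent (exception) items have rc < 0.5.  Imageability
    groups are the low/high tertiles of the imageability proxy.
    """
    df = word_results.merge(sr_scores[["ovs", "ove", "version", sr_col]],
                            on=["ovs", "ove", "version"])
    q1, q2 = np.quantile(df["img"], [1 / 3, 2 / 3])
    df = df[(df["img"] <= q1) | (df["img"] > q2)].copy()
    df["img_class"] = np.where(df["img"] <= q1, -0.5, 0.5)
    df = df[(df["rc"] == 1.0) | (df["rc"] < 0.5)].copy()
    # inconsistent - consistent coding
    df["cons_class"] = np.where(df["rc"] < 0.5, 0.5, -0.5)
    df = st.preprocess(df, "phon_sse", covariates=[sr_col])
    return st.factorial_sr_analysis(df, sr_col)


def analyze(results: GridResults) -> dict:
    """The full inferential battery over grid output.

    Returns a JSON-serialisable report: the pooled psycholinguistic LMM
    with the oral-knowledge comparison, SR distributions and their
    correlation, factorial interaction tables, OVE x OVS interaction
    regressions, and structural path models for both SR measures.
    """
    wr, scores = results.word_results, results.sr_scores
    report: dict = {}

    # pooled LMM: baseline psycholinguistic effects vs + oral knowledge
    covs = ["logwf", "ons", "rc", "img", "ove", "ovs"]
    clean = st.preprocess(wr, "phon_sse", covariates=covs)
    clean["wf_x_rc"] = clean["logwf"] * clean["rc"]
    base_formula = "phon_sse ~ logwf + ons + rc + img + wf_x_rc"
    ext_formula = base_formula + " + ove + ovs"
    base_ml = st.fit_lmm(clean, base_formula, reml=False)
    ext_ml = st.fit_lmm(clean, ext_formula, reml=False)
    chi2, dof, pval = st.compare_lmm(base_ml, ext_ml)
    report["lmm_reading"] = {
        "n_obs": ext_ml.n_obs,
        "coefficients": ext_ml.to_frame().to_dict(orient="index"),
        "lr_test": {"chi2": chi2, "df": dof, "p": pval},
    }

    # SR distributions and their correlation
    sr_summary = {}
    for col in ("eoc_sr", "dol_sr"):
        x = scores[col]
        sr_summary[col] = {"min": float(x.min()), "max": float(x.max()),
                           "mean": float(x.mean()),
                           "sd": float(x.std(ddof=1))}
    r, t_r, n = sr_correlation(scores)
    sr_summary["correlation"] = {"r": r, "t": t_r, "n": n}
    report["sr_distributions"] = sr_summary

    # factorial imageability x consistency x SR
    report["factorial"] = {}
    for col in ("eoc_sr", "dol_sr"):
        try:
            fit, cells = _factorial_table(wr, scores, col)
            report["factorial"][col] = {
                "coefficients": fit.to_frame().to_dict(orient="index"),
                "cell_means": cells.to_dict(orient="records"),
            }
        except st.StatsError as exc:
            report["factorial"][col] = {"error": str(exc)}

    # OVE x OVS -> SR interaction regressions and structural models
    report["sr_regressions"] = {}
    report["structural"] = {}
    for col in ("eoc_sr", "dol_sr"):
        fit = st.ols_interaction(scores, col)
        report["sr_regressions"][col] = {
            "r2": fit.r2, "adj_r2": fit.adj_r2,
            "coefficients": fit.to_frame().to_dict(orient="index"),
        }
        path = st.structural_model(scores, col)
        report["structural"][col] = {
            "chi2": path.chi2, "df": path.df, "cfi": path.cfi,
            "tli": path.tli, "rmsea": path.rmsea,
            "close_fit": path.close_fit,
            "paths": path.paths.to_dict(orient="records"),
        }
    return report


def sr_correlation(scores: pd.DataFrame) -> tuple[float, float, int]:
    """Pearson correlation between the two SR measures, with its t value."""
    n = len(scores)
    r = float(np.corrcoef(scores["eoc_sr"], scores["dol_sr"])[0, 1])
    t = r * np.sqrt((n - 2) / max(1.0 - r ** 2, 1e-12))
    return r, float(t), n


def save_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, default=float))
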