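"""Semantic-reliance (SR) measures per simulation.

Two indices quantify how much reading aloud leans on the semantic pathway:

* **EoCSR** — the psycholinguistic (effect-of-consistency) approach: within
  the low-imageability tertile of correctly read words, regress phonological
  SSE on rime consistency with log frequency and orthographic neighbourhood
  as controls, and take the consistency coefficient with its sign reversed.
  A strong consistency effect on hard (low-imageability) words signals a
  reader leaning on semantics.
* **DoLSR** — the division-of-labour approach: the mean absolute net input
  that the orthography->semantics route delivers into the semantic layer,
  divided by the sum of that and the orthography->phonology route's input
  into the phonological layer, both taken at the last time step of a
  reading trial and averaged over a probe set of words (default: the full
  lexicon).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .language import EncodedLexicon
from .network import (ActivationTrace, NetworkParams, forward_pass,
                      OP_FINAL_CONNECTION, OS_FINAL_CONNECTION)


class SRError(ValueError):
    pass


@dataclass
class EoCScore:
    """Sign-reversed consistency coefficient and its inferential context."""

    value: float
    se: float
    t: float
    n_used: int

    @property
    def significant(self) -> bool:
        return abs(self.t) > 1.96


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise SRError("zero variance in a regression variable")
    return (x - x.mean()) / sd


def eoc_sr(results: pd.DataFrame, standardize: bool = True,
           min_items: int = 10) -> EoCScore:
    """EoCSR from one simulation's per-word results.

    Splits words into imageability tertiles (ties to the lower tertile),
    keeps the low tertile, drops misread words and phonological-SSE
    outliers beyond 2 SD, then fits OLS of phonological SSE on rime
    consistency with log frequency and neighbourhood size as controls.
    Returns the rc coefficient sign-reversed; standardized (all variables
    z-scored) by default, or on the raw data scale.
    """
    required = {"phon_sse", "phon_correct", "rc", "logwf", "ons", "img"}
    missing = required - set(results.columns)
    if missing:
        raise SRError(f"results table missing columns {sorted(missing)}")
    df = results.dropna(subset=sorted(required)).copy()

    q1, q2 = np.quantile(df["img"], [1 / 3, 2 / 3])
    low = df[df["img"] <= q1]

    low = low[low["phon_correct"].astype(bool)]
    mu, sd = low["phon_sse"].mean(), low["phon_sse"].std(ddof=1)
    if sd > 0:
        low = low[(low["phon_sse"] - mu).abs() <= 2 * sd]
    if len(low) < min_items:
        raise SRError(f"only {len(low)} usable low-imageability items "
                      f"(need >= {min_items})")

    y = low["phon_sse"].to_numpy(dtype=float)
    X = low[["rc", "logwf", "ons"]].to_numpy(dtype=float)
    if standardize:
        y = _zscore(y)
        X = np.column_stack([_zscore(X[:, j]) for j in range(X.shape[1])])
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise SRError("collinear predictors in EoC regression")
    fit = sm.OLS(y, Xc).fit()
    return EoCScore(value=-float(fit.params[1]), se=float(fit.bse[1]),
                    t=float(fit.tvalues[1]), n_used=len(low))


def pathway_activation(trace: ActivationTrace,
                       connection: tuple[str, str],
                       step: int = -1) -> np.ndarray:
    """Mean over target-layer units of the absolute net input arriving via
    ``connection``, at ``step`` (default: final).  Returns one value per
    batch row."""
    if trace.contributions is None or connection not in trace.contributions:
        raise SRError(f"trace has no recorded contributions for {connection}")
    contrib = trace.contributions[connection][step]
    return np.abs(contrib).mean(axis=1)


def dol_sr(params: NetworkParams, enc: EncodedLexicon,
           items: np.ndarray | None = None,
           os_connection: tuple[str, str] = OS_FINAL_CONNECTION,
           op_connection: tuple[str, str] = OP_FINAL_CONNECTION,
           chunk: int = 64) -> float:
    """DoLSR = OS / (OS + OP) over a probe set (default: whole lexicon)."""
    orth = enc.orth if items is None else enc.orth[items]
    schedule = params.config.schedule("READ")
    os_vals, op_vals = [], []
    for lo in range(0, orth.shape[0], chunk):
        trace = forward_pass(params, schedule,
                             {"orthography": orth[lo:lo + chunk]},
                             record_contributions=True)
        os_vals.append(pathway_activation(trace, os_connection))
        op_vals.append(pathway_activation(trace, op_connection))
    os_mean = float(np.concatenate(os_vals).mean())
    op_mean = float(np.concatenate(op_vals).mean())
    if os_mean + op_mean == 0:
        raise SRError("zero total pathway activation")
    return os_mean / (os_mean + op_mean)
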