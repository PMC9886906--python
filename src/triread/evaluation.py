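"""Scoring of model outputs: SSE, nearest-neighbour decoding, accuracies.

Error scores are summed squared differences between the produced and target
activation patterns (the model's analogue of response latency).  Accuracy
uses nearest-neighbour decoding by Euclidean distance: per phoneme slot
against the phoneme inventory (including an all-zero null phoneme for empty
slots), and for semantics against every semantic vector in the training
set.  Nonword pronunciations count as correct when the decoded phoneme
string matches any attested pronunciation of the nonword's rime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .language import (EncodedLexicon, Lexicon, Nonword, N_PHON_SLOTS,
                       N_PHON_FEATURES, encode_orthography, log_frequency)
from .network import NetworkParams, forward_pass


def sse(actual: np.ndarray, target: np.ndarray) -> float:
    """Summed squared error between two equal-length patterns."""
    actual = np.asarray(actual, dtype=float)
    target = np.asarray(target, dtype=float)
    if actual.shape != target.shape:
        raise ValueError(f"shape mismatch {actual.shape} vs {target.shape}")
    return float(((actual - target) ** 2).sum())


def _inventory_matrix(inventory: dict[str, np.ndarray]):
    labels = list(inventory.keys())
    mat = np.stack([inventory[lb] for lb in labels])
    return labels, mat


def decode_phonemes(output: np.ndarray,
                    inventory: dict[str, np.ndarray]) -> tuple[str, ...]:
    """Per-slot nearest phoneme (Euclidean); ties -> lowest inventory index."""
    if not inventory:
        raise ValueError("empty phoneme inventory")
    labels, mat = _inventory_matrix(inventory)
    out = np.asarray(output, dtype=float).reshape(N_PHON_SLOTS,
                                                  N_PHON_FEATURES)
    # argmin over squared distances; np.argmin takes the first (lowest index)
    d2 = ((out[:, None, :] - mat[None, :, :]) ** 2).sum(axis=2)
    return tuple(labels[i] for i in np.argmin(d2, axis=1))


def decode_semantics(output: np.ndarray, sem_matrix: np.ndarray) -> int:
    """Index of the nearest training-set semantic vector (ties -> lowest)."""
    if sem_matrix.shape[0] == 0:
        raise ValueError("empty semantic training set")
    d2 = ((sem_matrix - np.asarray(output, dtype=float)[None, :]) ** 2).sum(axis=1)
    return int(np.argmin(d2))


def score_nonword(output: np.ndarray, nonword: Nonword,
                  inventory: dict[str, np.ndarray],
                  vowel_phonemes: set[str]) -> bool:
    """True when the decoded string matches ANY acceptable pronunciation."""
    from .language import phoneme_slots
    decoded = decode_phonemes(output, inventory)
    for pron in nonword.acceptable_pronunciations:
        if decoded == phoneme_slots(pron, vowel_phonemes):
            return True
    return False


@dataclass
class EvaluationSummary:
    acc_op: float            # reading aloud (orthography -> phonology)
    acc_os: float            # written word comprehension
    acc_sp: float            # meaning naming
    acc_ps: float            # oral comprehension
    nonword_acc: dict[str, float]
    mean_phon_sse: float
    mean_sem_sse: float

    def to_dict(self) -> dict:
        return {"acc_op": self.acc_op, "acc_os": self.acc_os,
                "acc_sp": self.acc_sp, "acc_ps": self.acc_ps,
                "nonword_acc": dict(self.nonword_acc),
                "mean_phon_sse": self.mean_phon_sse,
                "mean_sem_sse": self.mean_sem_sse}


def _batched_final(params: NetworkParams, task: str,
                   inputs: dict[str, np.ndarray], out_layers: list[str],
                   chunk: int = 64) -> dict[str, np.ndarray]:
    """Run a task over all rows in chunks; return final-step activations."""
    schedule = params.config.schedule(task)
    n = next(iter(inputs.values())).shape[0]
    outs: dict[str, list[np.ndarray]] = {ly: [] for ly in out_layers}
    for lo in range(0, n, chunk):
        sl = slice(lo, lo + chunk)
        trace = forward_pass(params, schedule,
                             {k: v[sl] for k, v in inputs.items()})
        for ly in out_layers:
            outs[ly].append(trace.final(ly))
    return {ly: np.concatenate(chunks) for ly, chunks in outs.items()}


def evaluate_model(params: NetworkParams, enc: EncodedLexicon,
                   nonwords: list[Nonword] | None = None,
                   chunk: int = 64) -> tuple[pd.DataFrame, EvaluationSummary]:
    """Per-word results plus task-level accuracy summaries.

    Output activations are taken at the final time step of each trial.
    Semantic decoding scores the context-designated meaning as correct
    (homophone forms that the orthography cannot disambiguate count
    against the model for all but one meaning).
    """
    lex = enc.lexicon
    inv = lex.phoneme_inventory
    vph = lex.vowel_phonemes
    n = len(lex)

    read_out = _batched_final(params, "READ", {"orthography": enc.orth},
                              ["phonology", "semantics"], chunk)
    sp_out = _batched_final(params, "SP", {"semantics": enc.sem},
                            ["phonology"], chunk)
    ps_out = _batched_final(params, "PS",
                            {"phonology": enc.phon, "context": enc.ctx},
                            ["semantics"], chunk)

    rows = []
    for i, item in enumerate(lex.items):
        phon_out = read_out["phonology"][i]
        sem_out = read_out["semantics"][i]
        decoded = decode_phonemes(phon_out, inv)
        phon_correct = decoded == enc.phon_slots[i]
        sem_correct = decode_semantics(sem_out, enc.sem) == i
        sp_correct = decode_phonemes(sp_out["phonology"][i],
                                     inv) == enc.phon_slots[i]
        ps_correct = decode_semantics(ps_out["semantics"][i], enc.sem) == i
        rows.append({
            "item_id": i,
            "letters": item.letters,
            "context_index": item.context_index,
            "phon_sse": sse(phon_out, enc.phon[i]),
            "sem_sse": sse(sem_out, enc.sem[i]),
            "phon_correct": phon_correct,
            "sem_correct": sem_correct,
            "sp_correct": sp_correct,
            "ps_correct": ps_correct,
            "wf": item.wf,
            "logwf": float(log_frequency(item.wf)),
            "ons": item.ons,
            "rc": item.rc,
            "img": item.img,
        })
    results = pd.DataFrame(rows)

    nonword_acc: dict[str, float] = {}
    if nonwords:
        by_cond: dict[str, list[Nonword]] = {}
        for nw in nonwords:
            by_cond.setdefault(nw.condition, []).append(nw)
        for cond, nws in by_cond.items():
            orth = np.stack([encode_orthography(nw.letters, lex.alphabet,
                                                lex.vowels) for nw in nws])
            out = _batched_final(params, "READ", {"orthography": orth},
                                 ["phonology"], chunk)["phonology"]
            flags = [score_nonword(out[j], nw, inv, vph)
                     for j, nw in enumerate(nws)]
            nonword_acc[cond] = float(np.mean(flags))

    summary = EvaluationSummary(
        acc_op=float(results["phon_correct"].mean()),
        acc_os=float(results["sem_correct"].mean()),
        acc_sp=float(results["sp_correct"].mean()),
        acc_ps=float(results["ps_correct"].mean()),
        nonword_acc=nonword_acc,
        mean_phon_sse=float(results["phon_sse"].mean()),
        mean_sem_sse=float(results["sem_sse"].mean()),
    )
    return results, summary
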