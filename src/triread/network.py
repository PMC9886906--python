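"""The recurrent triangle network and its two-phase training regime.

A discrete-time, synchronous, logistic-unit recurrent network links three
key layers — orthography, phonology, semantics — through five hidden layers
and two attractor (clean-up) layers:

* ``orthography -> h_op -> phonology`` (direct print-to-sound route)
* ``orthography -> h_os1 -> h_os2 -> semantics`` (print-to-meaning route,
  two hidden layers deep)
* ``phonology -> h_ps -> semantics`` (spoken-word comprehension), with the
  4 context units feeding ``h_ps`` to disambiguate homophone meanings
* ``semantics -> h_sp -> phonology`` (meaning naming)
* ``phonology <-> attr_p`` and ``semantics <-> attr_s`` attractors that
  drive layer activity toward learned stable patterns.

Training is online stochastic gradient descent with backpropagation through
time (BPTT) over the unrolled trial.  Phase one (oral language) interleaves
comprehension (PS), naming (SP) and the two attractor tasks 40/40/10/10 on
a frequency-weighted sample of the top-``ovs`` words.  Phase two (reading)
freezes every oral-phase parameter and trains the orthographic routes to
produce both phonological and semantic targets.

Per-trial clamping/target windows (1-indexed network time steps):

========  =====  ==================  =======================
task      steps  input clamped       targets scored
========  =====  ==================  =======================
PS / SP   8      steps 1-8           steps 7-8
PP / SS   8      steps 1-2           steps 3-8 (free-running)
READ      12     steps 1-12          steps 7-12 (P and S)
========  =====  ==================  =======================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.special

from .language import EncodedLexicon

ORTH, PHON, SEM, CTX = "orthography", "phonology", "semantics", "context"

ORAL_CONNECTIONS: tuple[tuple[str, str], ...] = (
    (PHON, "h_ps"), (CTX, "h_ps"), ("h_ps", SEM),
    (SEM, "h_sp"), ("h_sp", PHON),
    (PHON, "attr_p"), ("attr_p", PHON),
    (SEM, "attr_s"), ("attr_s", SEM),
)
READING_CONNECTIONS: tuple[tuple[str, str], ...] = (
    (ORTH, "h_op"), ("h_op", PHON),
    (ORTH, "h_os1"), ("h_os1", "h_os2"), ("h_os2", SEM),
)
# layers whose biases are trained in the oral phase (and frozen afterwards)
ORAL_BIAS_LAYERS = ("h_ps", "h_sp", "attr_p", "attr_s", PHON, SEM)

OP_FINAL_CONNECTION = ("h_op", PHON)
OS_FINAL_CONNECTION = ("h_os2", SEM)

TASKS = ("PS", "SP", "PP", "SS", "READ")
ORAL_TASKS = ("PS", "SP", "PP", "SS")
ORAL_TASK_MIXTURE = (0.4, 0.4, 0.1, 0.1)


class NetworkError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrialSchedule:
    """Clamping and target-scoring windows of one trial type.

    Windows are 1-indexed inclusive ``(start, end)`` over network time
    steps; a clamp window starting at step 1 also sets the initial state.
    """

    task: str
    total_steps: int
    clamp: dict[str, tuple[int, int]]
    targets: dict[str, tuple[int, int]]

    def clamped_at(self, layer: str, t: int) -> bool:
        win = self.clamp.get(layer)
        return win is not None and win[0] <= t <= win[1]


def make_schedule(task: str, attractor_full_window: bool = True) -> TrialSchedule:
    if task == "PS":
        return TrialSchedule("PS", 8, {PHON: (1, 8), CTX: (1, 8)},
                             {SEM: (7, 8)})
    if task == "SP":
        return TrialSchedule("SP", 8, {SEM: (1, 8)}, {PHON: (7, 8)})
    if task in ("PP", "SS"):
        layer = PHON if task == "PP" else SEM
        window = (3, 8) if attractor_full_window else (7, 8)
        return TrialSchedule(task, 8, {layer: (1, 2)}, {layer: window})
    if task == "READ":
        return TrialSchedule("READ", 12, {ORTH: (1, 12)},
                             {PHON: (7, 12), SEM: (7, 12)})
    raise NetworkError(f"unknown task {task!r}")


@dataclass
class NetworkConfig:
    """Layer sizes, wiring, schedules and training hyperparameters.

    ``hidden_sizes`` maps the five hidden layers and two attractors to unit
    counts.  Wiring is a data-driven connection table so alternative routes
    remain testable.  The training loss is cross-entropy by default
    (switchable to squared error); summed squared error is always the
    evaluation metric.
    """

    orth_size: int
    sem_size: int
    phon_size: int = 200
    context_size: int = 4
    hidden_sizes: dict[str, int] = field(default_factory=lambda: {
        "h_op": 60, "h_os1": 40, "h_os2": 40, "h_ps": 40, "h_sp": 40,
        "attr_p": 30, "attr_s": 30})
    connections: tuple[tuple[str, str], ...] = \
        ORAL_CONNECTIONS + READING_CONNECTIONS
    input_layers: tuple[str, ...] = (ORTH, CTX)
    init_range: float = 0.25
    learning_rate: float = 0.05
    loss: str = "cross_entropy"  # or "sse"
    attractor_full_window: bool = True

    @property
    def layer_sizes(self) -> dict[str, int]:
        sizes = {ORTH: self.orth_size, PHON: self.phon_size,
                 SEM: self.sem_size, CTX: self.context_size}
        sizes.update(self.hidden_sizes)
        return sizes

    def schedule(self, task: str) -> TrialSchedule:
        return make_schedule(task, self.attractor_full_window)

    def validate(self) -> None:
        sizes = self.layer_sizes
        for s, d in self.connections:
            if s not in sizes or d not in sizes:
                raise NetworkError(f"wiring references unknown layer ({s},{d})")
        if self.loss not in ("cross_entropy", "sse"):
            raise NetworkError(f"unknown loss {self.loss!r}")


def default_config(lexicon_or_enc, **overrides) -> NetworkConfig:
    lex = getattr(lexicon_or_enc, "lexicon", lexicon_or_enc)
    from .language import N_ORTH_SLOTS
    cfg = NetworkConfig(orth_size=N_ORTH_SLOTS * len(lex.alphabet),
                        sem_size=lex.n_sem_features, **overrides)
    cfg.validate()
    return cfg


@dataclass
class NetworkParams:
    """All pathway weights and biases, with per-parameter freeze flags."""

    config: NetworkConfig
    weights: dict[tuple[str, str], np.ndarray]   # (dst, src)-shaped
    biases: dict[str, np.ndarray]
    frozen: set = field(default_factory=set)     # connection tuples / layer names

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            config=self.config,
            weights={k: v.copy() for k, v in self.weights.items()},
            biases={k: v.copy() for k, v in self.biases.items()},
            frozen=set(self.frozen))

    def freeze_oral(self) -> None:
        """Fix every parameter trained in the oral phase (reading phase)."""
        self.frozen |= set(ORAL_CONNECTIONS)
        self.frozen |= set(ORAL_BIAS_LAYERS)

    def computed_layers(self) -> list[str]:
        return sorted({d for _, d in self.config.connections})

    def save(self, path) -> None:
        arrays = {}
        for (s, d), w in self.weights.items():
            arrays[f"W__{s}__{d}"] = w
        for layer, b in self.biases.items():
            arrays[f"b__{layer}"] = b
        arrays["frozen"] = np.array(
            ["|".join(k) if isinstance(k, tuple) else k
             for k in sorted(self.frozen, key=str)])
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path, config: NetworkConfig) -> "NetworkParams":
        data = np.load(path, allow_pickle=False)
        weights, biases = {}, {}
        for key in data.files:
            if key.startswith("W__"):
                _, s, d = key.split("__")
                weights[(s, d)] = data[key]
            elif key.startswith("b__"):
                biases[key[3:]] = data[key]
        frozen = {tuple(k.split("|")) if "|" in k else k
                  for k in data["frozen"].tolist()}
        return cls(config=config, weights=weights, biases=biases,
                   frozen=frozen)


def init_network(config: NetworkConfig,
                 seed: int | np.random.Generator = 0) -> NetworkParams:
    """I.i.d. uniform(-r, r) weights and biases; deterministic per seed."""
    config.validate()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sizes = config.layer_sizes
    r = config.init_range
    weights = {}
    for s, d in sorted(config.connections):
        weights[(s, d)] = rng.uniform(-r, r, size=(sizes[d], sizes[s]))
    biases = {layer: rng.uniform(-r, r, size=sizes[layer])
              for layer in sorted({d for _, d in config.connections})}
    return NetworkParams(config=config, weights=weights, biases=biases)


# --------------------------------------------------------------------------
# forward / backward
# --------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return scipy.special.expit(x)


@dataclass
class ActivationTrace:
    """Per-layer activations (and optional per-connection net-input
    contributions into each layer) at every time step of one trial."""

    schedule: TrialSchedule
    acts: list[dict[str, np.ndarray]]                     # index 0..T
    contributions: dict[tuple[str, str], list[np.ndarray]] | None = None

    def final(self, layer: str) -> np.ndarray:
        return self.acts[-1][layer]


def forward_pass(params: NetworkParams, schedule: TrialSchedule,
                 inputs: dict[str, np.ndarray],
                 active: tuple[tuple[str, str], ...] | None = None,
                 record_contributions: bool = False) -> ActivationTrace:
    """Run one (batched) trial; synchronous logistic updates each step.

    ``inputs`` must hold a pattern for every clamped layer, shaped
    ``(batch, layer_size)``.  Clamped layers are overridden by their input
    during the clamp window; pure input layers are zero when unclamped;
    unclamped computed layers start at 0.5.
    """
    cfg = params.config
    conns = cfg.connections if active is None else tuple(active)
    sizes = cfg.layer_sizes
    computed = sorted({d for _, d in conns})
    incoming = {d: [(s, d2) for (s, d2) in conns if d2 == d] for d in computed}

    batch = next(iter(inputs.values())).shape[0]
    for layer, pat in inputs.items():
        if pat.shape != (batch, sizes[layer]):
            raise NetworkError(
                f"input for {layer!r} has shape {pat.shape}, expected "
                f"{(batch, sizes[layer])}")

    def clamp_value(layer: str) -> np.ndarray:
        if layer not in inputs:
            raise NetworkError(f"clamped layer {layer!r} missing from inputs")
        return inputs[layer]

    state: dict[str, np.ndarray] = {}
    for layer in sizes:
        if schedule.clamped_at(layer, 1) and layer in schedule.clamp \
                and schedule.clamp[layer][0] == 1:
            state[layer] = clamp_value(layer)
        elif layer in computed:
            state[layer] = np.full((batch, sizes[layer]), 0.5)
        else:
            state[layer] = np.zeros((batch, sizes[layer]))

    acts = [state]
    contribs: dict[tuple[str, str], list[np.ndarray]] | None = None
    if record_contributions:
        contribs = {c: [np.zeros((batch, sizes[c[1]]))] for c in conns}

    for t in range(1, schedule.total_steps + 1):
        prev = acts[-1]
        new: dict[str, np.ndarray] = {}
        for layer in sizes:
            if layer in computed:
                net = np.broadcast_to(params.biases[layer],
                                      (batch, sizes[layer])).copy()
                for (s, d) in incoming[layer]:
                    contrib = prev[s] @ params.weights[(s, d)].T
                    net += contrib
                    if contribs is not None:
                        contribs[(s, d)].append(contrib)
                a = _sigmoid(net)
                if not np.all(np.isfinite(a)):
                    raise NetworkError(f"non-finite activation in {layer!r}")
                new[layer] = a
            else:
                new[layer] = np.zeros((batch, sizes[layer]))
        for layer in schedule.clamp:
            if schedule.clamped_at(layer, t):
                new[layer] = clamp_value(layer)
        acts.append(new)
    return ActivationTrace(schedule=schedule, acts=acts,
                           contributions=contribs)


_EPS = 1e-7


def loss_value(trace: ActivationTrace, targets: dict[str, np.ndarray],
               kind: str = "cross_entropy",
               windows: dict[str, tuple[int, int]] | None = None) -> float:
    """Sum over scored steps and units of the per-unit loss, meaned over
    the batch.  ``windows`` defaults to the schedule's target windows."""
    windows = windows or trace.schedule.targets
    total = 0.0
    batch = next(iter(targets.values())).shape[0]
    for layer, (t0, t1) in windows.items():
        if t1 > trace.schedule.total_steps:
            raise NetworkError("target window exceeds schedule length")
        y = targets[layer]
        for t in range(t0, t1 + 1):
            a = trace.acts[t][layer]
            if a.shape != y.shape:
                raise NetworkError(f"target shape mismatch for {layer!r}")
            if kind == "sse":
                total += float(((a - y) ** 2).sum())
            elif kind == "cross_entropy":
                ac = np.clip(a, _EPS, 1 - _EPS)
                total += float(-(y * np.log(ac)
                                 + (1 - y) * np.log(1 - ac)).sum())
            else:
                raise NetworkError(f"unknown loss kind {kind!r}")
    return total / batch


def bptt_gradient(params: NetworkParams, schedule: TrialSchedule,
                  inputs: dict[str, np.ndarray],
                  targets: dict[str, np.ndarray],
                  active: tuple[tuple[str, str], ...] | None = None,
                  loss_kind: str | None = None):
    """Backpropagation through time over the unrolled trial.

    Returns ``(grad_w, grad_b, loss)``; gradients are of the batch-mean
    loss with respect to every parameter on the active connections.
    Frozen parameters receive exactly zero gradient.
    """
    cfg = params.config
    kind = loss_kind or cfg.loss
    conns = cfg.connections if active is None else tuple(active)
    trace = forward_pass(params, schedule, inputs, active=conns)
    acts = trace.acts
    computed = sorted({d for _, d in conns})

    batch = next(iter(inputs.values())).shape[0]
    grad_w = {c: np.zeros_like(params.weights[c]) for c in conns}
    grad_b = {layer: np.zeros_like(params.biases[layer])
              for layer in computed}

    da_future: dict[str, np.ndarray] = {}
    loss = 0.0
    for t in range(schedule.total_steps, 0, -1):
        dnet_t: dict[str, np.ndarray] = {}
        for layer in computed:
            if schedule.clamped_at(layer, t):
                continue
            a = acts[t][layer]
            da = da_future.get(layer)
            scored = (layer in schedule.targets
                      and schedule.targets[layer][0] <= t
                      <= schedule.targets[layer][1])
            if scored and kind == "sse":
                term = 2.0 * (a - targets[layer])
                da = term if da is None else da + term
            dnet = np.zeros_like(a) if da is None else da * a * (1.0 - a)
            if scored and kind == "cross_entropy":
                dnet = dnet + (a - targets[layer])
            if scored or da is not None:
                dnet_t[layer] = dnet
        new_da: dict[str, np.ndarray] = {}
        for (s, d) in conns:
            if d not in dnet_t:
                continue
            grad_w[(s, d)] += dnet_t[d].T @ acts[t - 1][s]
            prev = new_da.get(s)
            back = dnet_t[d] @ params.weights[(s, d)]
            new_da[s] = back if prev is None else prev + back
        for layer, dn in dnet_t.items():
            grad_b[layer] += dn.sum(axis=0)
        da_future = new_da

    loss = loss_value(trace, targets, kind=kind)
    inv_b = 1.0 / batch
    for c in conns:
        grad_w[c] *= inv_b
        if c in params.frozen:
            grad_w[c][:] = 0.0
    for layer in computed:
        grad_b[layer] *= inv_b
        if layer in params.frozen:
            grad_b[layer][:] = 0.0
    return grad_w, grad_b, loss


def sgd_step(params: NetworkParams, grad_w, grad_b, lr: float) -> None:
    for c, g in grad_w.items():
        if c not in params.frozen:
            params.weights[c] -= lr * g
    for layer, g in grad_b.items():
        if layer not in params.frozen:
            params.biases[layer] -= lr * g


# --------------------------------------------------------------------------
# training phases
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OralCondition:
    """Oral vocabulary size (distinct spoken words trained) and exposure
    (total oral training trials)."""

    ovs: int
    ove: int


def _oral_batch(task: str, enc: EncodedLexicon, idx: np.ndarray):
    """(inputs, targets) arrays for one batch of one oral task."""
    if task == "PS":
        return ({"phonology": enc.phon[idx], "context": enc.ctx[idx]},
                {"semantics": enc.sem[idx]})
    if task == "SP":
        return {"semantics": enc.sem[idx]}, {"phonology": enc.phon[idx]}
    if task == "PP":
        return {"phonology": enc.phon[idx]}, {"phonology": enc.phon[idx]}
    if task == "SS":
        return {"semantics": enc.sem[idx]}, {"semantics": enc.sem[idx]}
    raise NetworkError(f"not an oral task: {task!r}")


def train_oral(params: NetworkParams, enc: EncodedLexicon,
               condition: OralCondition, rng: np.random.Generator,
               batch_size: int = 1, log_every: int = 0) -> list[dict]:
    """Phase one: interleaved PS/SP/PP/SS training on the top-``ovs`` words.

    Tasks are drawn 40/40/10/10 per update; words are drawn
    frequency-weighted with replacement from the ``ovs`` most frequent
    items.  Runs until ``condition.ove`` word presentations (trials) have
    been made; with ``batch_size`` b each update presents b words.
    """
    lex = enc.lexicon
    if condition.ovs > len(lex):
        raise NetworkError("ovs exceeds lexicon size")
    cfg = params.config
    top = lex.top_k_indices(condition.ovs)
    wf = lex.frequencies[top]
    probs = wf / wf.sum()
    schedules = {t: cfg.schedule(t) for t in ORAL_TASKS}
    mix = np.array(ORAL_TASK_MIXTURE)

    log: list[dict] = []
    done = 0
    update = 0
    while done < condition.ove:
        b = min(batch_size, condition.ove - done)
        task = ORAL_TASKS[rng.choice(4, p=mix)]
        idx = top[rng.choice(len(top), size=b, p=probs)]
        inputs, targets = _oral_batch(task, enc, idx)
        gw, gb, loss = bptt_gradient(params, schedules[task], inputs,
                                     targets, active=ORAL_CONNECTIONS)
        sgd_step(params, gw, gb, cfg.learning_rate)
        done += b
        update += 1
        if log_every and update % log_every == 0:
            log.append({"trial": done, "task": task, "loss": loss})
    return log


def train_reading(params: NetworkParams, enc: EncodedLexicon, n_trials: int,
                  rng: np.random.Generator, batch_size: int = 1,
                  log_every: int = 0) -> list[dict]:
    """Phase two: reading training over the whole lexicon.

    Orthography is clamped for 12 steps; phonological and semantic targets
    are scored on steps 7-12.  Only parameters not frozen after the oral
    phase (the orthographic routes) change.
    """
    lex = enc.lexicon
    cfg = params.config
    schedule = cfg.schedule("READ")
    wf = lex.frequencies
    probs = wf / wf.sum()

    log: list[dict] = []
    done = 0
    update = 0
    while done < n_trials:
        b = min(batch_size, n_trials - done)
        idx = rng.choice(len(lex), size=b, p=probs)
        inputs = {"orthography": enc.orth[idx]}
        targets = {"phonology": enc.phon[idx], "semantics": enc.sem[idx]}
        gw, gb, loss = bptt_gradient(params, schedule, inputs, targets)
        sgd_step(params, gw, gb, cfg.learning_rate)
        done += b
        update += 1
        if log_every and update % log_every == 0:
            log.append({"trial": done, "task": "READ", "loss": loss})
    return log
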