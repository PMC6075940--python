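"""A trainable associative learner shaped by all 16 decoded parameters.

The network maps a 557-unit verb encoding to a 62-unit past-tense
encoding through an architecture that may comprise a hidden layer, a
direct input-to-output pathway, or both.  Every non-input unit applies a
temperature-scaled logistic to its (noise-perturbed) net input.  Training
is per-pattern backpropagation under either a sum-squared or a
cross-entropy objective, with momentum, per-input-bank learning-rate
modifiers, multiplicative weight decay, sparse initial connectivity, and
probabilistic pruning of weak connections after an onset epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .artificial_language import AFFIX_CODES, AFFIXES, N_FEATURES, N_INPUT, N_OUTPUT, N_SLOTS
from .genome import ParameterSet

N_PHON_IN = N_SLOTS * N_FEATURES  # phonological input bank: units 0..56

#: legal affix codes in AFFIXES order, used when decoding generalisation responses
_AFFIX_CODE_MATRIX = np.array([AFFIX_CODES[a] for a in AFFIXES], dtype=np.float64)


class DivergenceError(RuntimeError):
    """Raised when training drives weights non-finite."""

    def __init__(self, parameters: ParameterSet):
        super().__init__(f"non-finite weights during training; parameters: {parameters.as_dict()}")
        self.parameters = parameters


@dataclass
class BehaviouralProfile:
    """Percent correct per verb class plus percent rule-correct novel allomorphs."""

    regular_pct: float
    no_change_pct: float
    vowel_change_pct: float
    arbitrary_pct: float
    novel_regularized_pct: float

    def as_tuple(self) -> tuple:
        return (self.regular_pct, self.no_change_pct, self.vowel_change_pct,
                self.arbitrary_pct, self.novel_regularized_pct)


@dataclass
class NetworkState:
    """Weight stores are input-major: W_ih is (n_inputs, n_hidden), W_ho is
    (n_hidden, n_outputs), W_io (direct pathway) is (n_inputs, n_outputs).
    V_* hold momentum velocities, M_* the connectivity masks (initial
    sparseness AND not-pruned); absent pathways hold zero-size arrays."""

    parameters: ParameterSet
    rng: np.random.Generator
    W_ih: np.ndarray
    V_ih: np.ndarray
    M_ih: np.ndarray
    b_h: np.ndarray
    Vb_h: np.ndarray
    W_ho: np.ndarray
    V_ho: np.ndarray
    M_ho: np.ndarray
    W_io: np.ndarray
    V_io: np.ndarray
    M_io: np.ndarray
    b_o: np.ndarray
    Vb_o: np.ndarray
    lr_col: np.ndarray              # per-input-column effective learning rate
    epoch_counter: int = 0

    @property
    def has_hidden(self) -> bool:
        return self.parameters.architecture != "direct_only"

    @property
    def has_direct(self) -> bool:
        return self.parameters.architecture != "hidden_only"

    def connection_count(self) -> int:
        return int(self.M_ih.sum() + self.M_ho.sum() + self.M_io.sum())

    def weights_finite(self) -> bool:
        return all(np.isfinite(a).all() for a in
                   (self.W_ih, self.b_h, self.W_ho, self.W_io, self.b_o))


def seed_noise(seed: int) -> None:
    """Seed the compiled kernels' noise/pruning random stream."""
    _kernels.seed_noise_rng(np.uint32(seed))


def init_network(parameters: ParameterSet, rng: np.random.Generator,
                 n_input: int = N_INPUT, n_output: int = N_OUTPUT,
                 dtype=np.float64) -> NetworkState:
    """Fresh network: uniform weights in +/- weight_variance, sparse masks.

    Each potential inter-layer connection is independently absent with
    probability ``sparseness``.  Biases (one per non-input unit) are
    always present and are exempt from sparseness and pruning.  ``dtype``
    selects the precision of the weight stores (population runs use
    single precision).
    """
    p = parameters
    dtype = np.dtype(dtype)
    has_hidden = p.architecture != "direct_only"
    has_direct = p.architecture != "hidden_only"
    n_hid = p.hidden_units if has_hidden else 0
    wv = p.weight_variance

    def pathway(shape, present):
        if not present:
            z = np.zeros((0, 0), dtype=dtype)
            return z, z.copy(), z.copy()
        W = rng.uniform(-wv, wv, size=shape)
        M = (rng.random(shape) >= p.sparseness).astype(dtype)
        W *= M
        return W.astype(dtype), np.zeros(shape, dtype=dtype), M

    W_ih, V_ih, M_ih = pathway((n_input, n_hid), has_hidden)
    W_ho, V_ho, M_ho = pathway((n_hid, n_output), has_hidden)
    W_io, V_io, M_io = pathway((n_input, n_output), has_direct)
    b_h = rng.uniform(-wv, wv, size=n_hid).astype(dtype)
    b_o = rng.uniform(-wv, wv, size=n_output).astype(dtype)

    lr_col = np.full(n_input, p.learning_rate * p.semantic_lr, dtype=dtype)
    lr_col[:N_PHON_IN] = p.learning_rate * p.phonological_lr

    return NetworkState(
        parameters=p, rng=rng,
        W_ih=W_ih, V_ih=V_ih, M_ih=M_ih, b_h=b_h, Vb_h=np.zeros(n_hid, dtype=dtype),
        W_ho=W_ho, V_ho=V_ho, M_ho=M_ho,
        W_io=W_io, V_io=V_io, M_io=M_io,
        b_o=b_o, Vb_o=np.zeros(n_output, dtype=dtype),
        lr_col=lr_col,
    )


def forward(state: NetworkState, x: np.ndarray, rng: np.random.Generator | None = None,
            with_noise: bool = False) -> np.ndarray:
    """Single-pattern forward pass (pure numpy; the oracle for the kernels).

    Each non-input unit computes net = sum(masked weights x activations)
    + bias (+ Gaussian noise when requested) and fires
    1 / (1 + exp(-net / temperature)).
    """
    p = state.parameters
    x = np.asarray(x, dtype=np.float64)
    noise = p.noise if with_noise else 0.0
    if noise > 0.0 and rng is None:
        raise ValueError("with_noise=True requires an rng")

    net_o = state.b_o.astype(np.float64)
    if state.has_hidden:
        net_h = x @ state.W_ih + state.b_h
        if noise > 0.0:
            net_h = net_h + rng.normal(0.0, noise, size=net_h.shape)
        a_h = 1.0 / (1.0 + np.exp(-net_h / p.temperature))
        net_o = net_o + a_h @ state.W_ho
    if state.has_direct:
        net_o = net_o + x @ state.W_io
    if noise > 0.0:
        net_o = net_o + rng.normal(0.0, noise, size=net_o.shape)
    return 1.0 / (1.0 + np.exp(-net_o / p.temperature))


def pattern_loss(state: NetworkState, x: np.ndarray, t: np.ndarray) -> float:
    """Noise-free objective for one pattern (sum-squared or cross-entropy)."""
    a = forward(state, x, with_noise=False)
    t = np.asarray(t, dtype=np.float64)
    if state.parameters.learning_algorithm == "cross_entropy":
        eps = 1e-300
        return float(-(t * np.log(a + eps) + (1 - t) * np.log(1 - a + eps)).sum())
    return float(0.5 * ((a - t) ** 2).sum())


def binary_csr(X: np.ndarray) -> tuple:
    """CSR (indptr, indices) of the active units of binary pattern rows."""
    X = np.asarray(X)
    if not np.isin(X, (0, 1)).all():
        raise ValueError("training patterns must be binary")
    indptr = np.zeros(len(X) + 1, dtype=np.int64)
    cols = []
    for i, row in enumerate(X):
        nz = np.flatnonzero(row)
        cols.append(nz)
        indptr[i + 1] = indptr[i] + len(nz)
    return indptr, np.concatenate(cols).astype(np.int64)


def train_epoch(state: NetworkState, X: np.ndarray, T: np.ndarray,
                order: np.ndarray | None = None,
                csr: tuple | None = None) -> NetworkState:
    """One shuffled pass over the family patterns, updating in place.

    The presentation order is drawn from the child's own rng stream
    unless given explicitly.  ``csr`` optionally supplies the precomputed
    :func:`binary_csr` of X.  Raises :class:`DivergenceError` if weights
    go non-finite.
    """
    if len(X) == 0:
        raise ValueError("empty pattern set")
    p = state.parameters
    ft = state.b_o.dtype.type
    if order is None:
        order = state.rng.permutation(len(X))
    indptr, indices = csr if csr is not None else binary_csr(X)
    _kernels.train_epoch_kernel(
        indptr, indices, np.asarray(order, dtype=np.int64),
        np.ascontiguousarray(T, dtype=state.b_o.dtype),
        state.W_ih, state.V_ih, state.M_ih, state.b_h, state.Vb_h,
        state.W_ho, state.V_ho, state.M_ho,
        state.W_io, state.V_io, state.M_io,
        state.b_o, state.Vb_o,
        state.lr_col, ft(p.learning_rate), ft(p.momentum), ft(p.weight_decay),
        ft(p.temperature), ft(p.noise),
        p.learning_algorithm == "cross_entropy",
        state.has_hidden, state.has_direct)
    state.epoch_counter += 1
    if not state.weights_finite():
        raise DivergenceError(p)
    return state


def apply_pruning(state: NetworkState) -> int:
    """End-of-epoch regressive event; a no-op before the onset epoch.

    From the onset onward, every surviving connection whose magnitude is
    below the pruning threshold is permanently removed with the pruning
    probability.  Returns the number of connections removed.
    """
    p = state.parameters
    if state.epoch_counter < p.pruning_onset or p.pruning_probability <= 0.0:
        return 0
    removed = 0
    ft = state.b_o.dtype.type
    for W, V, M in ((state.W_ih, state.V_ih, state.M_ih),
                    (state.W_ho, state.V_ho, state.M_ho),
                    (state.W_io, state.V_io, state.M_io)):
        if W.size:
            removed += _kernels.prune_kernel(W, V, M, ft(p.pruning_threshold),
                                             ft(p.pruning_probability))
    return removed


def score_response(output: np.ndarray, target: np.ndarray, response_threshold: float) -> bool:
    """Correct iff every output unit is within the threshold of its binary target."""
    output = np.asarray(output, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if output.shape != target.shape:
        raise ValueError("output/target length mismatch")
    return bool(np.max(np.abs(output - target)) <= response_threshold)


def prepare_patterns(patterns: dict, dtype=np.float64) -> dict:
    """Precompute the stacked, dtype-cast assessment arrays once per run."""
    dtype = np.dtype(dtype)
    return {
        "X_all": np.ascontiguousarray(
            np.vstack([patterns["X_train"], patterns["X_novel"]]), dtype=dtype),
        "T_train": np.ascontiguousarray(patterns["T_train"], dtype=dtype),
        "class_idx": np.ascontiguousarray(patterns["class_idx"], dtype=np.int64),
        "class_counts": np.bincount(patterns["class_idx"], minlength=4).astype(np.float64),
        "novel_allomorph": np.ascontiguousarray(patterns["novel_allomorph"], dtype=np.int64),
    }


def evaluate(state: NetworkState, patterns: dict, with_noise: bool = False) -> BehaviouralProfile:
    """Standardised assessment on the full corpus and the novel set.

    Always run against all 500 verbs regardless of the child's family
    subset.  By default the assessment measures competence without the
    processing-noise perturbation (noise shapes learning, not the test;
    with noise at test a noisy-but-competent child could never reach the
    ceiling scores the population distribution shows).  Pass
    ``with_noise=True`` to test under noise instead.  Novel items are
    judged on whether their affix units decode to the rule-correct
    allomorph.  ``patterns`` is either the corpus pattern dict or the
    output of :func:`prepare_patterns`.
    """
    p = state.parameters
    if "X_all" not in patterns:
        patterns = prepare_patterns(patterns, dtype=state.b_o.dtype)
    ft = state.b_o.dtype.type
    vals = _kernels.eval_kernel(
        patterns["X_all"], patterns["T_train"], patterns["class_idx"],
        patterns["class_counts"], patterns["novel_allomorph"],
        _AFFIX_CODE_MATRIX.astype(state.b_o.dtype),
        state.W_ih, state.b_h, state.W_ho, state.W_io, state.b_o,
        ft(p.temperature), ft(p.noise), ft(p.response_threshold),
        state.has_hidden, state.has_direct, with_noise)
    return BehaviouralProfile(*[float(v) for v in vals])
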