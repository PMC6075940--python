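"""Compiled inner loops for training, pruning and assessment.

These kernels implement the per-pattern arithmetic of the learner —
stochastic backpropagation with momentum, per-pathway learning-rate
modifiers, multiplicative weight decay, Gaussian net-input noise and a
temperature-scaled logistic — so that whole-population runs stay
tractable on one CPU.  The public API in :mod:`.network` wraps them;
tests exercise the same code path at toy sizes.

Weight stores are input-major: the input->hidden pathway has shape
(n_inputs, n_hidden), hidden->output (n_hidden, n_outputs) and the
direct pathway (n_inputs, n_outputs), so all per-input-column work is
contiguous.

Because inputs are binary and sparse, the momentum/decay recurrence for
a weight whose gradient is zero,

    v <- m v,   w <- (w + v) (1 - lambda),

is applied lazily per input column in closed form (geometric sums,
precomputed per gap length), which is arithmetically equivalent to the
per-pattern update and avoids touching every weight on every pattern.

The kernels are dtype-generic: weight stores and scalars must share one
floating dtype (float64 by default; population runs use float32).
Noise draws use numba's process-global generator; seed it per child with
:func:`seed_noise_rng` for reproducibility.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def seed_noise_rng(seed):
    np.random.seed(seed)


@njit(cache=False, fastmath=True)
def _sync_column(W, V, col, k, apow, bpow, coef, tiny):
    """Advance one lazy column by k gradient-free momentum/decay steps."""
    if k <= 0:
        return
    ak = apow[k]
    bk = bpow[k]
    ck = coef[k]
    zero = ak * np.float64(0.0)
    n = W.shape[1]
    for i in range(n):
        v = V[col, i]
        W[col, i] = ak * W[col, i] + ck * v
        v = bk * v
        if -tiny < v < tiny:
            v = zero
        V[col, i] = v


@njit(cache=False, fastmath=True)
def train_epoch_kernel(indptr, indices, order, T,
                       W_ih, V_ih, M_ih, b_h, Vb_h,
                       W_ho, V_ho, M_ho, W_io, V_io, M_io, b_o, Vb_o,
                       lr_col, lr, mom, decay, temperature, noise_sd,
                       use_ce, has_hidden, has_direct):
    """One pass over the family patterns in the given presentation order.

    Patterns are binary input vectors in CSR form (indptr/indices over
    the unshuffled pattern list; ``order`` gives the presentation
    sequence; ``T`` holds the unshuffled targets).  Per pattern: forward
    with Gaussian net-input noise, backpropagate the chosen objective
    (sum-squared or cross-entropy), update each present connection with
    momentum (velocity form: v <- m v - eta g; w <- w + v) and
    per-input-bank learning rates, then apply multiplicative weight
    decay.  Masked (absent or pruned) connections stay exactly zero.
    """
    n_pat = order.shape[0]
    n_out = b_o.shape[0]
    n_hid = b_h.shape[0]
    n_in = lr_col.shape[0]
    one = b_o.dtype.type(1.0)
    zero = b_o.dtype.type(0.0)
    tiny = b_o.dtype.type(1e-30)    # flush-to-zero floor: avoids denormal stalls
    dc = one - decay
    inv_t = one / temperature

    # gap tables for the lazy column updates: after k gradient-free steps
    # v_k = b^k v_0 and w_k = a^k w_0 + coef_k v_0, with a = 1 - decay,
    # b = momentum, coef_k = a (coef_{k-1} + b^k).
    apow = np.empty(n_pat + 1, dtype=b_o.dtype)
    bpow = np.empty(n_pat + 1, dtype=b_o.dtype)
    coef = np.empty(n_pat + 1, dtype=b_o.dtype)
    af = np.float64(dc)
    bf = np.float64(mom)
    ap, bp, cf = 1.0, 1.0, 0.0
    apow[0], bpow[0], coef[0] = one, one, zero
    for k in range(1, n_pat + 1):
        ap *= af
        bp *= bf
        cf = af * (cf + bp)
        apow[k] = ap
        bpow[k] = bp
        coef[k] = cf

    upd = np.zeros(n_in, dtype=np.int64)   # per-column applied-update count

    a_h = np.zeros(n_hid, dtype=b_o.dtype)
    delta_o = np.zeros(n_out, dtype=b_o.dtype)
    for s in range(n_pat):
        p = order[s]
        nz = indices[indptr[p]:indptr[p + 1]]
        t = T[p]

        # ---- bring touched columns up to date ----
        for j in nz:
            k = s - upd[j]
            if has_hidden:
                _sync_column(W_ih, V_ih, j, k, apow, bpow, coef, tiny)
            if has_direct:
                _sync_column(W_io, V_io, j, k, apow, bpow, coef, tiny)
            upd[j] = s

        # ---- forward ----
        if has_hidden:
            net_h = np.zeros(n_hid, dtype=b_o.dtype)
            for j in nz:
                for i in range(n_hid):
                    net_h[i] += W_ih[j, i]
            for i in range(n_hid):
                z = net_h[i] + b_h[i]
                if noise_sd > 0.0:
                    z += np.random.normal(0.0, noise_sd)
                a_h[i] = one / (one + np.exp(-z * inv_t))
            net_o = np.dot(a_h, W_ho)
        else:
            net_o = np.zeros(n_out, dtype=b_o.dtype)
        if has_direct:
            for j in nz:
                for o in range(n_out):
                    net_o[o] += W_io[j, o]

        # ---- output activations and deltas (dE/dnet) ----
        for o in range(n_out):
            z = net_o[o] + b_o[o]
            if noise_sd > 0.0:
                z += np.random.normal(0.0, noise_sd)
            a = one / (one + np.exp(-z * inv_t))
            if use_ce:
                delta_o[o] = (a - t[o]) * inv_t
            else:
                delta_o[o] = (a - t[o]) * a * (one - a) * inv_t

        # ---- updates ----
        if has_hidden:
            delta_h = np.dot(W_ho, delta_o)
            for i in range(n_hid):
                delta_h[i] *= a_h[i] * (one - a_h[i]) * inv_t

            for i in range(n_hid):
                d = lr * a_h[i]
                for o in range(n_out):
                    v = M_ho[i, o] * (mom * V_ho[i, o] - d * delta_o[o])
                    if -tiny < v < tiny:
                        v = zero
                    V_ho[i, o] = v
                    W_ho[i, o] = (W_ho[i, o] + v) * dc
            for j in nz:
                lrj = lr_col[j]
                for i in range(n_hid):
                    v = M_ih[j, i] * (mom * V_ih[j, i] - lrj * delta_h[i])
                    if -tiny < v < tiny:
                        v = zero
                    V_ih[j, i] = v
                    W_ih[j, i] = (W_ih[j, i] + v) * dc
            for i in range(n_hid):
                v = mom * Vb_h[i] - lr * delta_h[i]
                if -tiny < v < tiny:
                    v = zero
                Vb_h[i] = v
                b_h[i] = (b_h[i] + v) * dc

        if has_direct:
            for j in nz:
                lrj = lr_col[j]
                for o in range(n_out):
                    v = M_io[j, o] * (mom * V_io[j, o] - lrj * delta_o[o])
                    if -tiny < v < tiny:
                        v = zero
                    V_io[j, o] = v
                    W_io[j, o] = (W_io[j, o] + v) * dc

        for o in range(n_out):
            v = mom * Vb_o[o] - lr * delta_o[o]
            if -tiny < v < tiny:
                v = zero
            Vb_o[o] = v
            b_o[o] = (b_o[o] + v) * dc

        for j in nz:
            upd[j] = s + 1

    # ---- bring every column up to date before pruning/assessment ----
    for j in range(n_in):
        k = n_pat - upd[j]
        if has_hidden:
            _sync_column(W_ih, V_ih, j, k, apow, bpow, coef, tiny)
        if has_direct:
            _sync_column(W_io, V_io, j, k, apow, bpow, coef, tiny)


@njit(cache=False)
def prune_kernel(W, V, M, threshold, prob):
    """Remove surviving sub-threshold connections with the given probability.

    Removal is permanent: weight, velocity and mask are zeroed.  Returns
    the number of connections removed.
    """
    removed = 0
    n, m = W.shape
    for i in range(n):
        for j in range(m):
            if M[i, j] != 0.0 and np.abs(W[i, j]) < threshold:
                if np.random.random() < prob:
                    M[i, j] = 0.0
                    W[i, j] = 0.0
                    V[i, j] = 0.0
                    removed += 1
    return removed


@njit(cache=False, fastmath=True)
def eval_kernel(X_all, T_train, class_idx, class_counts, novel_allo, affix_codes,
                W_ih, b_h, W_ho, W_io, b_o,
                temperature, noise_sd, theta, has_hidden, has_direct, with_noise):
    """Batched assessment against the full corpus plus the novel set.

    Training items are correct when every output unit is within the
    response threshold of its binary target.  Novel items are scored on
    the affix units only: the 5 units are thresholded at 0.5 and matched
    to the nearest legal affix code (ties resolved toward the earlier
    code in the none < t < d < syllabic order).

    Returns (regular, no_change, vowel_change, arbitrary, novel) percent
    correct.
    """
    n_all = X_all.shape[0]
    n_train = T_train.shape[0]
    n_out = b_o.shape[0]
    n_hid = b_h.shape[0]
    one = X_all.dtype.type(1.0)
    inv_t = one / temperature
    n_affix = affix_codes.shape[1]
    phon_out = n_out - n_affix
    noisy = with_noise and noise_sd > 0.0

    if has_hidden:
        A_H = np.dot(X_all, W_ih)
        for i in range(n_all):
            for h in range(n_hid):
                z = A_H[i, h] + b_h[h]
                if noisy:
                    z += np.random.normal(0.0, noise_sd)
                A_H[i, h] = one / (one + np.exp(-z * inv_t))
        A_O = np.dot(A_H, W_ho)
        if has_direct:
            A_O += np.dot(X_all, W_io)
    else:
        A_O = np.dot(X_all, W_io)
    for i in range(n_all):
        for o in range(n_out):
            z = A_O[i, o] + b_o[o]
            if noisy:
                z += np.random.normal(0.0, noise_sd)
            A_O[i, o] = one / (one + np.exp(-z * inv_t))

    cls_correct = np.zeros(4)
    for i in range(n_train):
        ok = True
        for o in range(n_out):
            if np.abs(A_O[i, o] - T_train[i, o]) > theta:
                ok = False
                break
        if ok:
            cls_correct[class_idx[i]] += 1.0

    novel_correct = 0
    n_novel = n_all - n_train
    for j in range(n_novel):
        row = n_train + j
        best = 0
        best_d = n_affix + 1
        for c in range(affix_codes.shape[0]):
            d = 0
            for u in range(n_affix):
                bit = 1.0 if A_O[row, phon_out + u] >= 0.5 else 0.0
                if bit != affix_codes[c, u]:
                    d += 1
            if d < best_d:
                best_d = d
                best = c
        if best == novel_allo[j]:
            novel_correct += 1

    profile = np.zeros(5)
    for c in range(4):
        if class_counts[c] > 0:
            profile[c] = 100.0 * cls_correct[c] / class_counts[c]
    if n_novel > 0:
        profile[4] = 100.0 * novel_correct / n_novel
    return profile
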