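"""Independent brute-force reference implementations.

Everything here is written with explicit Python loops and scalar math —
deliberately sharing no code with the vectorized package implementations
it is used to check.
"""

import math

import numpy as np


def sigmoid_s(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x)) if x >= 0 else math.exp(x) / (1.0 + math.exp(x))


def conv_oracle(X, kernels, biases, act):
    """Nested-loop text convolution: one output list per width, entry
    [i, f] = act(sum(kernel_f * window_i) + bias_f)."""
    n = X.shape[0]
    out = []
    for h in sorted(kernels):
        K, b = kernels[h], biases[h]
        F = K.shape[0]
        fmap = np.zeros((n - h + 1, F))
        for i in range(n - h + 1):
            for f in range(F):
                s = b[f]
                for j in range(h):
                    for k in range(X.shape[1]):
                        s += K[f, j, k] * X[i + j, k]
                fmap[i, f] = act(s)
        out.append(fmap)
    return out


def lstm_scalar_step(x, h, c, W_z, W_i, W_f, W_o, b_z, b_i, b_f, b_o):
    """Scalar-by-scalar LSTM recurrence."""
    hx = list(h) + list(x)
    H = len(h)
    h_new = np.zeros(H)
    c_new = np.zeros(H)
    for u in range(H):
        z = math.tanh(sum(W_z[u][j] * hx[j] for j in range(len(hx))) + b_z[u])
        i = sigmoid_s(sum(W_i[u][j] * hx[j] for j in range(len(hx))) + b_i[u])
        f = sigmoid_s(sum(W_f[u][j] * hx[j] for j in range(len(hx))) + b_f[u])
        o = sigmoid_s(sum(W_o[u][j] * hx[j] for j in range(len(hx))) + b_o[u])
        c_new[u] = f * c[u] + i * z
        h_new[u] = o * math.tanh(c_new[u])
    return h_new, c_new


def lstm_scalar_sequence(X, params_dict, hidden):
    h = np.zeros(hidden)
    c = np.zeros(hidden)
    outs = []
    for t in range(X.shape[0]):
        h, c = lstm_scalar_step(X[t], h, c, **params_dict)
        outs.append(h.copy())
    return np.array(outs), h, c


def gru_scalar_step(x, h, W_z, W_r, W):
    hx = list(h) + list(x)
    H = len(h)
    z = np.array([sigmoid_s(sum(W_z[u][j] * hx[j] for j in range(len(hx))))
                  for u in range(H)])
    r = np.array([sigmoid_s(sum(W_r[u][j] * hx[j] for j in range(len(hx))))
                  for u in range(H)])
    rh_x = list(r * h) + list(x)
    cand = np.array([math.tanh(sum(W[u][j] * rh_x[j] for j in range(len(rh_x))))
                     for u in range(H)])
    return (1.0 - z) * h + z * cand


def gru_scalar_sequence(X, W_z, W_r, W, hidden):
    h = np.zeros(hidden)
    outs = []
    for t in range(X.shape[0]):
        h = gru_scalar_step(X[t], h, W_z, W_r, W)
        outs.append(h.copy())
    return np.array(outs)


def bigru_oracle(X, fwd_w, bwd_w, hidden):
    """Two independent unidirectional scalar runs; the backward one sees
    the reversed input and its outputs are re-reversed before per-step
    concatenation."""
    f = gru_scalar_sequence(X, *fwd_w, hidden)
    b = gru_scalar_sequence(X[::-1], *bwd_w, hidden)[::-1]
    return np.concatenate([f, b], axis=1)


def softmax_vec(e):
    m = max(e)
    ex = [math.exp(v - m) for v in e]
    s = sum(ex)
    return [v / s for v in ex]


def hybrid_attention_oracle(H, W_r, v_a, b):
    """Direct evaluation: e_i = v_a . tanh(W_r h_i + b); w = softmax(e);
    context = sum_i w_i h_i."""
    T = H.shape[0]
    e = []
    for i in range(T):
        proj = [math.tanh(sum(W_r[u][j] * H[i][j] for j in range(H.shape[1])) + b[u])
                for u in range(len(v_a))]
        e.append(sum(v_a[u] * proj[u] for u in range(len(v_a))))
    w = softmax_vec(e)
    ctx = np.zeros(H.shape[1])
    for i in range(T):
        ctx += w[i] * H[i]
    return ctx, np.array(w)


def sda_oracle(Q, K, V):
    """Nested-loop scaled dot-product attention."""
    n, d = Q.shape
    out = np.zeros((n, V.shape[1]))
    for i in range(n):
        scores = [sum(Q[i][k] * K[j][k] for k in range(d)) / math.sqrt(d)
                  for j in range(K.shape[0])]
        w = softmax_vec(scores)
        for j in range(K.shape[0]):
            out[i] += w[j] * V[j]
    return out


def multihead_oracle(Q, K, V, W_q, W_k, W_v, W_o):
    heads = [sda_oracle(Q @ wq, K @ wk, V @ wv)
             for wq, wk, wv in zip(W_q, W_k, W_v)]
    return np.concatenate(heads, axis=1) @ W_o


def confusion_tally(pred, truth, n_classes):
    """Independent per-pair tally of one-vs-rest counts."""
    per = {c: {"TP": 0, "TN": 0, "FP": 0, "FN": 0} for c in range(n_classes)}
    for p, t in zip(pred, truth):
        for c in range(n_classes):
            if p == c and t == c:
                per[c]["TP"] += 1
            elif p == c and t != c:
                per[c]["FP"] += 1
            elif p != c and t == c:
                per[c]["FN"] += 1
            else:
                per[c]["TN"] += 1
    return per
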