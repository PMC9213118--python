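"""Independent brute-force oracles used by the tests.

Everything here is written as explicit loops over kernel taps and pixels —
deliberately naive, sharing no code with the package implementation.
"""

import numpy as np


def conv2d_oracle(x, weight, bias=None, dilation=1):
    """Direct sliding-window convolution with "same" zero padding.

    x: (N, H, W, Cin); weight: (kh, kw, Cin, Cout); taps are spaced
    ``dilation`` pixels apart.
    """
    n, h, w, cin = x.shape
    kh, kw, _, cout = weight.shape
    ph = dilation * (kh - 1) // 2
    pw = dilation * (kw - 1) // 2
    out = np.zeros((n, h, w, cout), dtype=np.float64)
    for b in range(n):
        for i in range(h):
            for j in range(w):
                for oc in range(cout):
                    acc = 0.0
                    for ki in range(kh):
                        for kj in range(kw):
                            ii = i + dilation * ki - ph
                            jj = j + dilation * kj - pw
                            if 0 <= ii < h and 0 <= jj < w:
                                for ic in range(cin):
                                    acc += x[b, ii, jj, ic] * weight[ki, kj, ic, oc]
                    out[b, i, j, oc] = acc
    if bias is not None:
        out += bias
    return out


def bn_eval_oracle(x, running_mean, running_var, gamma, beta, eps=1e-5):
    """Inference-mode batch normalization, channel by channel."""
    out = np.empty_like(x, dtype=np.float64)
    for c in range(x.shape[-1]):
        out[..., c] = (x[..., c] - running_mean[c]) / np.sqrt(
            running_var[c] + eps) * gamma[c] + beta[c]
    return out


def _sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


def scse_oracle(x, fc1_w, fc1_b, fc2_w, fc2_b, sp_w, sp_b):
    """Hand-rolled concurrent spatial + channel squeeze-excitation.

    Channel gate: global average pool -> fc1 -> ReLU -> fc2 -> sigmoid.
    Spatial gate: 1x1 conv to one channel -> sigmoid.  Combine by addition.
    """
    n, h, w, c = x.shape
    out = np.zeros_like(x, dtype=np.float64)
    for b in range(n):
        z = np.array([x[b, :, :, ch].mean() for ch in range(c)])
        hidden = np.maximum(z @ fc1_w + fc1_b, 0.0)
        s = _sigmoid(hidden @ fc2_w + fc2_b)
        for i in range(h):
            for j in range(w):
                q = _sigmoid(float(x[b, i, j, :] @ sp_w[0, 0, :, 0]) + sp_b[0])
                for ch in range(c):
                    out[b, i, j, ch] = x[b, i, j, ch] * s[ch] + x[b, i, j, ch] * q
    return out


def finite_difference_grads(loss_fn, param_arrays, indices_per_array=3,
                            eps=1e-6, seed=42):
    """Central-difference gradients of ``loss_fn()`` at sampled entries.

    ``param_arrays`` maps names to the arrays the loss depends on (mutated
    in place while probing).  Returns {name: [(flat_index, grad), ...]}.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for name, arr in param_arrays.items():
        flat = arr.ravel()
        idxs = rng.choice(flat.size, size=min(indices_per_array, flat.size),
                          replace=False)
        entries = []
        for i in idxs:
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss_fn()
            flat[i] = orig - eps
            lm = loss_fn()
            flat[i] = orig
            entries.append((int(i), (lp - lm) / (2 * eps)))
        out[name] = entries
    return out
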