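"""Independent straight-line numpy reference implementations.

Everything here is written as plainly as possible (explicit loops, no
shared code with the package's compute engine) and is used as the oracle
side of dual-route checks: the engine's convolution, normalization,
pooling, interpolation, loss and full forward pass are compared against
these on tiny inputs.
"""

import numpy as np


def ref_conv3x3(x, w, b):
    """Same-padded stride-1 correlation via explicit loops. x: (C,H,W)."""
    c_in, h, wd = x.shape
    c_out = w.shape[0]
    xp = np.zeros((c_in, h + 2, wd + 2), dtype=x.dtype)
    xp[:, 1:-1, 1:-1] = x
    out = np.zeros((c_out, h, wd), dtype=x.dtype)
    for k in range(c_out):
        for i in range(h):
            for j in range(wd):
                acc = 0.0
                for c in range(c_in):
                    for u in range(3):
                        for v in range(3):
                            acc += w[k, c, u, v] * xp[c, i + u, j + v]
                out[k, i, j] = acc + b[k]
    return out


def ref_conv1x1(x, w, b):
    c_out = w.shape[0]
    h, wd = x.shape[1], x.shape[2]
    out = np.zeros((c_out, h, wd), dtype=x.dtype)
    for k in range(c_out):
        for c in range(x.shape[0]):
            out[k] += w[k, c, 0, 0] * x[c]
        out[k] += b[k]
    return out


def ref_instance_norm(x, gamma, beta, eps=1e-5):
    """x: (C,H,W); per-channel normalization of a single sample."""
    out = np.empty_like(x)
    for c in range(x.shape[0]):
        mu = x[c].mean()
        var = ((x[c] - mu) ** 2).mean()
        out[c] = gamma[c] * (x[c] - mu) / np.sqrt(var + eps) + beta[c]
    return out


def ref_leaky(x, slope=0.01):
    return np.where(x > 0, x, slope * x)


def ref_maxpool2(x):
    c, h, w = x.shape
    out = np.zeros((c, h // 2, w // 2), dtype=x.dtype)
    for ch in range(c):
        for i in range(h // 2):
            for j in range(w // 2):
                out[ch, i, j] = x[ch, 2 * i:2 * i + 2, 2 * j:2 * j + 2].max()
    return out


def ref_bilinear_up(x, factor):
    """Pointwise bilinear up-sampling, half-pixel-centres convention."""
    c, h, w = x.shape
    ho, wo = h * factor, w * factor
    out = np.zeros((c, ho, wo), dtype=np.float64)
    for ch in range(c):
        for i in range(ho):
            for j in range(wo):
                sy = min(max((i + 0.5) / factor - 0.5, 0.0), h - 1.0)
                sx = min(max((j + 0.5) / factor - 0.5, 0.0), w - 1.0)
                y0, x0 = int(np.floor(sy)), int(np.floor(sx))
                y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
                fy, fx = sy - y0, sx - x0
                out[ch, i, j] = (
                    x[ch, y0, x0] * (1 - fy) * (1 - fx)
                    + x[ch, y0, x1] * (1 - fy) * fx
                    + x[ch, y1, x0] * fy * (1 - fx)
                    + x[ch, y1, x1] * fy * fx
                )
    return out


def ref_node(x, params, eps=1e-5):
    """Two-conv stage node on a single (C,H,W) sample.

    ``params`` is a dict with w1,b1,g1,be1,w2,b2,g2,be2.
    """
    h = ref_leaky(ref_instance_norm(
        ref_conv3x3(x, params["w1"], params["b1"]),
        params["g1"], params["be1"], eps))
    return ref_leaky(ref_instance_norm(
        ref_conv3x3(h, params["w2"], params["b2"]),
        params["g2"], params["be2"], eps))


def ref_dice_ce(logits, labels, eps=1e-5, include_background=False):
    """Cross-entropy + (1 - mean soft Dice), batch-aggregated per class."""
    n, c, h, w = logits.shape
    p = np.zeros_like(logits, dtype=np.float64)
    for b in range(n):
        for i in range(h):
            for j in range(w):
                z = logits[b, :, i, j] - logits[b, :, i, j].max()
                e = np.exp(z)
                p[b, :, i, j] = e / e.sum()
    ce = 0.0
    for b in range(n):
        for i in range(h):
            for j in range(w):
                ce -= np.log(max(p[b, labels[b, i, j], i, j], 1e-12))
    ce /= n * h * w
    fg = range(c) if (include_background or c == 1) else range(1, c)
    dices = []
    for cls in fg:
        inter = psum = tsum = 0.0
        for b in range(n):
            for i in range(h):
                for j in range(w):
                    t = 1.0 if labels[b, i, j] == cls else 0.0
                    inter += p[b, cls, i, j] * t
                    psum += p[b, cls, i, j]
                    tsum += t
        dices.append((2 * inter + eps) / (psum + tsum + eps))
    return ce + 1.0 - float(np.mean(dices))


def two_stage_forward(image, pre_p, node_ps, post_p, divisors, eps=1e-5):
    """Straight-line trace of the explicit-backbone forward pass for one
    sample: y0 = pre(image); e_i = node_i(concat of max-pooled y0 and
    previous increments); y1 = y0 + sum of bilinearly up-sampled e_i;
    logits = post(y1)."""
    y0 = ref_node(image, pre_p, eps)

    def down(t, steps):
        for _ in range(steps):
            t = ref_maxpool2(t)
        return t

    es = []
    for i, div in enumerate(divisors):
        steps = int(np.log2(div))
        inputs = [down(y0, steps)]
        for j in range(i):
            prev_steps = int(np.log2(divisors[j]))
            if div >= divisors[j]:
                inputs.append(down(es[j], steps - prev_steps))
            else:
                inputs.append(
                    ref_bilinear_up(es[j], divisors[j] // div)
                )
        es.append(ref_node(np.concatenate(inputs, axis=0), node_ps[i], eps))
    y1 = y0.astype(np.float64).copy()
    for e, div in zip(es, divisors):
        y1 += ref_bilinear_up(e, div)
    h = ref_leaky(ref_instance_norm(
        ref_conv3x3(y1, post_p["w1"], post_p["b1"]),
        post_p["g1"], post_p["be1"], eps))
    h = ref_leaky(ref_instance_norm(
        ref_conv3x3(h, post_p["w2"], post_p["b2"]),
        post_p["g2"], post_p["be2"], eps))
    return ref_conv1x1(h, post_p["wc"], post_p["bc"])
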