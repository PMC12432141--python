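"""Independent brute-force oracles used across the test suite.

Each reimplements a pipeline stage the slow, obvious way (explicit loops,
full sorts, hand interpolation) so the vectorized implementations can be
checked against code that shares none of their machinery.
"""

import numpy as np


def dense_gaussian_blur(img, kernel, sigma):
    """O(n^2 k^2) direct 2-D convolution with mirror (reflect-101) padding."""
    x = np.arange(kernel) - (kernel - 1) / 2.0
    w1 = np.exp(-(x**2) / (2.0 * sigma**2))
    w1 /= w1.sum()
    k2 = np.outer(w1, w1)
    r = kernel // 2
    pad = np.pad(np.asarray(img, dtype=float), r, mode="reflect")
    h, w = img.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in range(kernel):
                for b in range(kernel):
                    acc += pad[i + a, j + b] * k2[a, b]
            out[i, j] = acc
    return out


def twopass_threshold(img, sd_mult=5.0):
    """Scalar two-pass mean/SD plus an explicit comparison loop."""
    flat = [float(v) for row in np.asarray(img, dtype=float) for v in row]
    n = len(flat)
    mean = sum(flat) / n
    var = sum((v - mean) ** 2 for v in flat) / n
    t = mean + sd_mult * var**0.5
    out = np.asarray(img, dtype=float).copy()
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            if out[i, j] < t:
                out[i, j] = 0.0
    return out


def loop_block_mean(img, block=2):
    """Nested-loop non-overlapping block averaging."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    out = np.zeros((h // block, w // block))
    for i in range(h // block):
        for j in range(w // block):
            s = 0.0
            for a in range(block):
                for b in range(block):
                    s += img[i * block + a, j * block + b]
            out[i, j] = s / block**2
    return out


def sorted_percentile(values, q):
    """Full sort + linear interpolation at rank (n-1)*q/100."""
    v = sorted(float(x) for x in np.asarray(values).ravel())
    n = len(v)
    rank = (n - 1) * q / 100.0
    lo = int(np.floor(rank))
    hi = min(lo + 1, n - 1)
    frac = rank - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def rank_auc(clean, artifact):
    """Mann-Whitney AUC: P(artifact > clean) + 0.5 P(tie), by counting."""
    clean = np.asarray(clean, dtype=float)
    artifact = np.asarray(artifact, dtype=float)
    wins = ties = 0
    for a in artifact:
        wins += int(np.sum(a > clean))
        ties += int(np.sum(a == clean))
    return (wins + 0.5 * ties) / (len(clean) * len(artifact))
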