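"""Independent reference implementations used only as test oracles.

These are deliberately naive, literal transcriptions of the defining
formulas — plain double loops and explicit convolutions — kept separate
from (and never calling into) the package's own implementations.
"""

from __future__ import annotations

import math

import numpy as np


def brute_sampen(x, m: int, r: float) -> float:
    """Sample entropy by explicit pair enumeration.

    B counts unordered pairs of length-m templates (drawn from the first
    N-m templates, self-matches excluded) whose Chebyshev distance is
    <= r; A does the same at length m+1; SampEn = -ln(A/B).
    """
    x = list(map(float, x))
    n_templates = len(x) - m

    def pairs(length: int) -> int:
        templates = [x[i:i + length] for i in range(n_templates)]
        count = 0
        for i in range(n_templates):
            for j in range(i + 1, n_templates):
                d = max(abs(a - b) for a, b in zip(templates[i], templates[j]))
                if d <= r:
                    count += 1
        return count

    b = pairs(m)
    a = pairs(m + 1)
    return -math.log(a / b)


def brute_apen(x, m: int, r: float) -> float:
    """Approximate entropy by explicit template-frequency averaging.

    C_i^m(r) is the fraction of templates (self included) within r of
    template i; Phi^m is the mean of log C_i^m; ApEn = Phi^m - Phi^(m+1).
    """
    x = list(map(float, x))
    n = len(x)

    def phi(length: int) -> float:
        n_templates = n - length + 1
        templates = [x[i:i + length] for i in range(n_templates)]
        total = 0.0
        for i in range(n_templates):
            c = 0
            for j in range(n_templates):
                d = max(abs(a - b) for a, b in zip(templates[i], templates[j]))
                if d <= r:
                    c += 1
            total += math.log(c / n_templates)
        return total / n_templates

    return phi(m) - phi(m + 1)


def naive_dwt_level(x, lo, hi):
    """One analysis level by explicit symmetric padding and convolution.

    Half-point symmetric extension by taps-1 samples on each side, full
    convolution with each analysis filter, then stride-2 downsampling
    starting at index ``taps``; output length floor((N + taps - 1) / 2).
    """
    x = np.asarray(x, dtype=float)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    taps = len(lo)
    out_len = (len(x) + taps - 1) // 2
    ext = np.pad(x, (taps - 1, taps - 1), mode="symmetric")
    approx = np.convolve(ext, lo)[taps::2][:out_len]
    detail = np.convolve(ext, hi)[taps::2][:out_len]
    return approx, detail
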