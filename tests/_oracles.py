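"""Independent oracles kept separate from the implementations they check."""

from __future__ import annotations

import numpy as np


def womersley_series(grad_amplitude: float, alpha: float, phase: float,
                     y: np.ndarray, half_width: float = 1.0,
                     density: float = 1.0, nu: float = 1.0,
                     n_terms: int = 50000) -> np.ndarray:
    """Eigenfunction-expansion solution of driven oscillatory channel flow.

    Expands the unit forcing in the no-slip cosine eigenbasis
    ``cos((n+1/2) pi y / h)`` and sums the per-mode driven responses — an
    evaluation route fully independent of the cosh closed form.
    """
    omega = alpha ** 2 * nu / half_width ** 2
    n = np.arange(n_terms)
    mu = (n + 0.5) * np.pi / half_width
    a = 2.0 * (-1.0) ** n / ((n + 0.5) * np.pi)
    c = (grad_amplitude / density) * a / (1j * omega + nu * mu ** 2)
    y = np.atleast_1d(np.asarray(y, dtype=float))
    basis = np.cos(np.outer(y, mu))
    return np.real(basis @ c * np.exp(1j * phase))


def confusion_counts_bruteforce(flags, labels):
    """Count TP/FP/TN/FN by explicit case-by-case enumeration."""
    tp = fp = tn = fn = 0
    for f, l in zip(flags, labels):
        if f and l:
            tp += 1
        elif f and not l:
            fp += 1
        elif not f and l:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn
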