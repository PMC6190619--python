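"""Small nonparametric helpers used for sampler initial values."""

from __future__ import annotations

import numpy as np


def nelson_aalen(time, event) -> tuple[np.ndarray, np.ndarray]:
    """Nelson-Aalen cumulative hazard at the distinct event times.

    Returns (event_times, H). Used only to seed MCMC starting values.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    t_sorted, e_sorted = time[order], event[order]
    n = len(t_sorted)
    at_risk = n - np.arange(n)
    uniq = np.unique(t_sorted[e_sorted == 1])
    H = np.empty_like(uniq)
    acc = 0.0
    for i, u in enumerate(uniq):
        mask = t_sorted == u
        d = int(e_sorted[mask].sum())
        r = int(at_risk[np.argmax(mask)])
        acc += d / r
        H[i] = acc
    return uniq, H
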