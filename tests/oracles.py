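"""Independent line-by-line transcriptions of the published stock
recursions, used only as cross-checks against the strategy engine.

These deliberately mirror the printed equations (1-based weeks, dict-backed
stock maps, explicit floor/max/min) rather than the engine's vectorised
bookkeeping, so agreement is informative.
"""
from __future__ import annotations

import math
from typing import Mapping, Sequence


def oracle_ideal(P: Sequence[int], W_init: int, t0: int = 5) -> dict[int, int]:
    """W^I recursion: r_t = min(W_t / sum_{s>t} P_s, 1);
    W_{t+1} = max(W_t - floor(r_t * P_t), 0)."""
    T = len(P)
    W = {t0: W_init}
    for t in range(t0, T + 1):
        future = sum(P[s - 1] for s in range(t + 1, T + 1))
        r = 1.0 if future == 0 else min(W[t] / future, 1.0)
        W[t + 1] = max(W[t] - math.floor(r * P[t - 1]), 0)
    return W


def oracle_main(
    P: Sequence[int],
    forecasts: Mapping[int, Sequence[float]],
    W_init: int,
    t0: int = 5,
) -> dict[int, int]:
    """W^M recursion: the ideal rule with the true future total replaced by
    sum_{s>t} P_hat_s(t); a zero predicted total gives rate 1."""
    T = len(P)
    W = {t0: W_init}
    for t in range(t0, T + 1):
        demand = sum(forecasts[t]) if t < T else 0.0
        r = 1.0 if demand <= 0 else min(W[t] / demand, 1.0)
        W[t + 1] = max(W[t] - math.floor(r * P[t - 1]), 0)
    return W


def oracle_s1(P: Sequence[int], W_init: int, t0: int = 5) -> dict[int, int]:
    """W^{S1} recursion: W_{t+1} = W_t - min(floor(W_t / 2), P_t)."""
    T = len(P)
    W = {t0: W_init}
    for t in range(t0, T + 1):
        W[t + 1] = W[t] - min(math.floor(W[t] / 2), P[t - 1])
    return W


def oracle_s2(P: Sequence[int], W_init: int, t0: int = 5) -> dict[int, int]:
    """W^{S2} recursion: W_{t+1} = W_t - min(floor(W_t / (T - t)), P_t);
    in the final week the whole remaining stock is offered."""
    T = len(P)
    W = {t0: W_init}
    for t in range(t0, T + 1):
        share = W[t] if t == T else math.floor(W[t] / (T - t))
        W[t + 1] = W[t] - min(share, P[t - 1])
    return W
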