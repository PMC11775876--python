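"""Seeded tree-structured Parzen estimator (TPE) for hyperparameter search.

Minimises a black-box objective over a box of ordinal hyperparameters.
After a uniform start-up phase, observed trials are split into a "good"
quantile and the rest. Each dimension is modelled with an adaptive Parzen
estimator: a Gaussian mixture over the observed values with per-point
bandwidths set by neighbour spacing, plus a full-span prior component at
the box centre that keeps the search exploring. Candidates are drawn from
the good-trial mixture l(x) and the candidate maximising the density ratio
l(x)/g(x) against the bad-trial mixture is evaluated next. Dimensions are
treated independently, as in the classic TPE formulation.
"""
from __future__ import annotations

from typing import Callable

import numpy as np


def _adaptive_parzen(values: np.ndarray, lo: float, hi: float):
    """Mixture (means, sigmas) over observed values plus the box-centre prior."""
    span = hi - lo
    mus = np.concatenate([values, [(lo + hi) / 2.0]])
    order = np.argsort(mus, kind="stable")
    sorted_mus = mus[order]
    n = len(sorted_mus)
    sigmas = np.empty(n)
    if n == 1:
        sigmas[0] = span
    else:
        left = np.diff(sorted_mus, prepend=sorted_mus[0] - span)
        right = np.diff(sorted_mus, append=sorted_mus[-1] + span)
        sigmas = np.maximum(left, right)
    sigmas = np.clip(sigmas, span / min(100.0, n + 1.0), span)
    # the prior component always keeps a full-span bandwidth
    prior_pos = int(np.nonzero(order == len(values))[0][0])
    sigmas[prior_pos] = span
    return sorted_mus, sigmas


def _mixture_sample(
    mus: np.ndarray, sigmas: np.ndarray, size: int, lo: float, hi: float,
    rng: np.random.Generator,
) -> np.ndarray:
    idx = rng.integers(0, len(mus), size=size)
    draw = rng.normal(mus[idx], sigmas[idx])
    return np.clip(draw, lo, hi)


def _mixture_logpdf(x: np.ndarray, mus: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    d = (x[:, None] - mus[None, :]) / sigmas[None, :]
    log_k = -0.5 * d**2 - np.log(sigmas[None, :] * np.sqrt(2 * np.pi))
    m = log_k.max(axis=1, keepdims=True)
    return m[:, 0] + np.log(np.exp(log_k - m).sum(axis=1)) - np.log(len(mus))


def _finalize(params: dict, space: dict, integer_params: tuple[str, ...]) -> dict:
    out = {}
    for name, (lo, hi) in space.items():
        v = float(np.clip(params[name], lo, hi))
        out[name] = int(round(v)) if name in integer_params else v
    return out


def tpe_minimize(
    objective: Callable[[dict], float],
    space: dict[str, tuple[float, float]],
    n_evals: int,
    rng: np.random.Generator,
    integer_params: tuple[str, ...] = (),
    n_startup: int = 15,
    gamma: float = 0.25,
    n_candidates: int = 24,
) -> tuple[dict, float, list[tuple[dict, float]]]:
    """Run ``n_evals`` objective evaluations; return (best_params, best_loss, trials)."""
    trials: list[tuple[dict, float]] = []
    for t in range(n_evals):
        if t < n_startup or len(trials) < 4:
            raw = {name: rng.uniform(lo, hi) for name, (lo, hi) in space.items()}
        else:
            losses = np.array([l for _, l in trials])
            order = np.argsort(losses, kind="stable")
            n_good = max(2, int(np.ceil(gamma * len(trials))))
            good_i, bad_i = order[:n_good], order[n_good:]
            raw = {}
            for name, (lo, hi) in space.items():
                good = np.array([trials[i][0][name] for i in good_i], dtype=float)
                bad = np.array([trials[i][0][name] for i in bad_i], dtype=float)
                mus_g, sig_g = _adaptive_parzen(good, lo, hi)
                mus_b, sig_b = _adaptive_parzen(bad, lo, hi)
                cand = _mixture_sample(mus_g, sig_g, n_candidates, lo, hi, rng)
                score = _mixture_logpdf(cand, mus_g, sig_g) - _mixture_logpdf(
                    cand, mus_b, sig_b
                )
                raw[name] = float(cand[int(np.argmax(score))])
        params = _finalize(raw, space, integer_params)
        loss = float(objective(params))
        trials.append((params, loss))
    best_params, best_loss = min(trials, key=lambda pl: pl[1])
    return best_params, best_loss, trials
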