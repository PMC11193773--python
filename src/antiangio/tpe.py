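"""A tree-structured Parzen estimator (TPE) sampler for hyperparameter search.

Sequential model-based optimization: finished trials are split into a "good"
fraction (top gamma by score) and the rest; each parameter gets a pair of
Parzen (kernel-density) estimators l(x) over the good trials and g(x) over the
bad ones, and the next value maximizes the density ratio l(x)/g(x) over a
candidate set drawn from l.  Parameters are treated independently; numeric
parameters may live on a log scale; integers are rounded; categoricals use
smoothed frequency ratios.  The first ``n_startup`` trials are drawn uniformly
at random.  All randomness comes from one seeded generator, so a search is
reproducible given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["Real", "Int", "Categorical", "TPESampler"]


@dataclass(frozen=True)
class Real:
    name: str
    low: float
    high: float
    log: bool = False


@dataclass(frozen=True)
class Int:
    name: str
    low: int
    high: int
    log: bool = False


@dataclass(frozen=True)
class Categorical:
    name: str
    choices: tuple

    def __init__(self, name, choices):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "choices", tuple(choices))


ParamSpec = Real | Int | Categorical


class TPESampler:
    def __init__(self, space: Sequence[ParamSpec], seed: int = 0,
                 n_startup: int = 10, gamma: float = 0.25, n_candidates: int = 24):
        names = [p.name for p in space]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        self.space = list(space)
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates

    # -- helpers -----------------------------------------------------------
    def _sample_uniform(self, p: ParamSpec):
        if isinstance(p, Categorical):
            return p.choices[self.rng.integers(len(p.choices))]
        lo, hi = (np.log(p.low), np.log(p.high)) if p.log else (p.low, p.high)
        v = self.rng.uniform(lo, hi)
        v = np.exp(v) if p.log else v
        return int(round(v)) if isinstance(p, Int) else float(v)

    def _to_internal(self, p: ParamSpec, v):
        return np.log(v) if getattr(p, "log", False) else float(v)

    def _from_internal(self, p: ParamSpec, v):
        out = float(np.exp(v)) if p.log else float(v)
        if isinstance(p, Int):
            out = int(np.clip(round(out), p.low, p.high))
        else:
            out = float(np.clip(out, p.low, p.high))
        return out

    @staticmethod
    def _log_parzen(x: np.ndarray, centers: np.ndarray, bw: float) -> np.ndarray:
        """Log density of an equal-weight Gaussian mixture at points x."""
        z = (x[:, None] - centers[None, :]) / bw
        log_k = -0.5 * z ** 2 - np.log(bw * np.sqrt(2 * np.pi))
        m = log_k.max(axis=1, keepdims=True)
        return (m[:, 0] + np.log(np.exp(log_k - m).sum(axis=1))) - np.log(len(centers))

    def _suggest_numeric(self, p, good_vals, bad_vals):
        lo, hi = (np.log(p.low), np.log(p.high)) if p.log else (p.low, p.high)
        span = hi - lo
        g = np.array([self._to_internal(p, v) for v in good_vals])
        b = np.array([self._to_internal(p, v) for v in bad_vals])

        def bw(points):
            s = points.std()
            return max(s * len(points) ** -0.2, 0.05 * span, 1e-12)

        bw_g, bw_b = bw(g), bw(b)
        idx = self.rng.integers(len(g), size=self.n_candidates)
        cand = np.clip(g[idx] + self.rng.normal(0, bw_g, self.n_candidates), lo, hi)
        score = self._log_parzen(cand, g, bw_g) - self._log_parzen(cand, b, bw_b)
        return self._from_internal(p, cand[int(np.argmax(score))])

    def _suggest_categorical(self, p, good_vals, bad_vals):
        def probs(vals):
            counts = np.array([1.0 + sum(v == c for v in vals) for c in p.choices])
            return counts / counts.sum()

        ratio = probs(good_vals) / probs(bad_vals)
        return p.choices[int(np.argmax(ratio))]

    # -- public ------------------------------------------------------------
    def suggest(self, history: Sequence[tuple[dict, float]]) -> dict:
        """Propose the next parameter set given (params, score) history.

        ``history`` holds finished trials only (higher score = better); pruned
        or failed trials should be omitted by the caller.
        """
        finished = [(par, s) for par, s in history if np.isfinite(s)]
        if len(finished) < self.n_startup:
            return {p.name: self._sample_uniform(p) for p in self.space}
        finished.sort(key=lambda t: t[1], reverse=True)
        n_good = max(1, int(np.ceil(self.gamma * len(finished))))
        good = [par for par, _ in finished[:n_good]]
        bad = [par for par, _ in finished[n_good:]] or good
        out = {}
        for p in self.space:
            gv = [d[p.name] for d in good]
            bv = [d[p.name] for d in bad]
            if isinstance(p, Categorical):
                out[p.name] = self._suggest_categorical(p, gv, bv)
            else:
                out[p.name] = self._suggest_numeric(p, gv, bv)
        return out
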