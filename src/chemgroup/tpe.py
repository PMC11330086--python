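"""A compact Tree-structured Parzen Estimator (TPE) sampler.

Bayesian optimization for the clustering / projection hyperparameter search.
After a seeded random start-up phase, observed trials are split by objective
value into a "good" top fraction (gamma) and the rest; each hyperparameter
is modeled independently by Parzen density estimates l(x) over the good
trials and g(x) over the bad ones. Candidate values are drawn from l and the
candidate maximizing the density ratio l(x)/g(x) is proposed. Supports
float, int, and categorical dimensions; maximizes the objective.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TPESampler"]


def _normal_pdf(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    z = (x[:, None] - mu[None, :]) / sigma[None, :]
    return np.exp(-0.5 * z * z) / (sigma[None, :] * np.sqrt(2 * np.pi))


class TPESampler:
    """Propose hyperparameters for a maximization problem.

    Parameters
    ----------
    space : dict
        name -> ("float", low, high) | ("int", low, high) | ("cat", choices).
    seed : int
        Seeds all sampling; identical histories yield identical proposals.
    n_startup : int
        Trials drawn uniformly at random before the Parzen model kicks in.
    gamma : float
        Fraction of trials considered "good".
    n_candidates : int
        Candidates drawn from l(x) per proposal.
    """

    def __init__(
        self,
        space: dict[str, tuple],
        seed: int = 0,
        n_startup: int = 10,
        gamma: float = 0.25,
        n_candidates: int = 24,
    ):
        self.space = dict(space)
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates
        for name, dim in self.space.items():
            kind = dim[0]
            if kind in ("float", "int"):
                if not dim[1] <= dim[2]:  # low == high pins the parameter
                    raise ValueError(f"{name}: low must be <= high")
            elif kind == "cat":
                if not dim[1]:
                    raise ValueError(f"{name}: empty choices")
            else:
                raise ValueError(f"{name}: unknown dimension kind {kind!r}")

    # -- random sampling ---------------------------------------------------

    def _random_value(self, dim: tuple):
        kind = dim[0]
        if kind == "float":
            return float(self.rng.uniform(dim[1], dim[2]))
        if kind == "int":
            return int(self.rng.integers(dim[1], dim[2] + 1))
        return dim[1][self.rng.integers(len(dim[1]))]

    def random_params(self) -> dict:
        return {n: self._random_value(d) for n, d in self.space.items()}

    # -- TPE proposal ------------------------------------------------------

    def _propose_numeric(self, dim: tuple, good: np.ndarray, bad: np.ndarray):
        low, high = float(dim[1]), float(dim[2])
        span = high - low
        if span == 0:
            return int(low) if dim[0] == "int" else low

        def mixture(obs: np.ndarray):
            # Parzen mixture over observations plus a uniform prior component
            sigma = max(span / np.sqrt(len(obs) + 1), 1e-6 * span)
            return obs, np.full(len(obs), sigma)

        mu_g, sig_g = mixture(good)
        cand = []
        for _ in range(self.n_candidates):
            if self.rng.random() < 1.0 / (len(good) + 1):
                cand.append(self.rng.uniform(low, high))
            else:
                i = self.rng.integers(len(good))
                cand.append(np.clip(self.rng.normal(mu_g[i], sig_g[i]), low, high))
        cand = np.asarray(cand)

        def density(x, obs):
            if len(obs) == 0:
                return np.full(len(x), 1.0 / span)
            mu, sig = mixture(obs)
            pdf = _normal_pdf(x, mu, sig).mean(axis=1)
            return (pdf * len(obs) + 1.0 / span) / (len(obs) + 1)

        ratio = density(cand, good) / np.maximum(density(cand, bad), 1e-300)
        best = cand[int(np.argmax(ratio))]
        if dim[0] == "int":
            return int(np.clip(round(best), dim[1], dim[2]))
        return float(best)

    def _propose_categorical(self, dim: tuple, good: list, bad: list):
        choices = dim[1]
        cg = np.array([good.count(c) for c in choices], dtype=float) + 1.0
        cb = np.array([bad.count(c) for c in choices], dtype=float) + 1.0
        ratio = (cg / cg.sum()) / (cb / cb.sum())
        weights = cg / cg.sum()
        idx = self.rng.choice(len(choices), size=self.n_candidates, p=weights)
        return choices[int(max(idx, key=lambda i: ratio[i]))]

    def suggest(self, history: list[tuple[dict, float]]) -> dict:
        """Next parameter set given (params, objective) pairs observed so far.

        In discrete spaces the density ratio can keep pointing at an
        already-evaluated configuration; since the objective is
        deterministic per configuration, such duplicates are wasted trials
        and are replaced by a random draw.
        """
        scored = [(p, s) for p, s in history if np.isfinite(s)]
        if len(scored) < self.n_startup:
            return self.random_params()
        proposal = self._suggest_model(scored)
        seen = {tuple(sorted(p.items())) for p, _ in history}
        if tuple(sorted(proposal.items())) in seen:
            return self.random_params()
        return proposal

    def _suggest_model(self, scored: list[tuple[dict, float]]) -> dict:
        scored.sort(key=lambda t: t[1], reverse=True)
        n_good = max(1, int(np.ceil(self.gamma * len(scored))))
        good, bad = scored[:n_good], scored[n_good:]
        if not bad:
            return self.random_params()
        params = {}
        for name, dim in self.space.items():
            gv = [t[0][name] for t in good if name in t[0]]
            bv = [t[0][name] for t in bad if name in t[0]]
            if not gv or not bv:
                params[name] = self._random_value(dim)
            elif dim[0] == "cat":
                params[name] = self._propose_categorical(dim, gv, bv)
            else:
                params[name] = self._propose_numeric(
                    dim, np.asarray(gv, dtype=float), np.asarray(bv, dtype=float)
                )
        return params
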