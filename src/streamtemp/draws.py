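"""Containers for MCMC output and posterior-predictive series."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def split_rhat(x: np.ndarray) -> float:
    """Potential scale reduction factor (split-chain Gelman-Rubin).

    ``x`` has shape (chains, iterations); each chain is split in half so the
    statistic is also sensitive to within-chain trends.
    """
    x = np.asarray(x, float)
    c, n = x.shape
    if c < 2:
        raise ValueError("at least 2 chains required")
    if n < 4:
        raise ValueError("at least 4 iterations per chain required")
    half = n // 2
    parts = np.concatenate([x[:, :half], x[:, n - half :]], axis=0)
    m, n2 = parts.shape
    means = parts.mean(axis=1)
    w = parts.var(axis=1, ddof=1).mean()
    b = n2 * means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else np.inf
    var_plus = (n2 - 1) / n2 * w + b / n2
    return float(np.sqrt(var_plus / w))


class PosteriorDraws:
    """Labelled MCMC draws.

    ``draws`` maps a parameter name to an array of shape ``(chains, kept)``
    for scalar parameters or ``(chains, kept, k)`` for vector-valued blocks
    (per-window means and amplitudes, latent missing cells, ...).
    """

    def __init__(self, draws: dict, meta: dict | None = None):
        self.draws = draws
        self.meta = meta or {}

    def names(self):
        return list(self.draws)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[name]

    def __contains__(self, name: str) -> bool:
        return name in self.draws

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_kept(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled across chains: shape (chains*kept,) or (chains*kept, k)."""
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    def iter_scalars(self):
        """Yield (label, (chains, kept) array) over all scalar components."""
        for name, a in self.draws.items():
            if a.ndim == 2:
                yield name, a
            else:
                for j in range(a.shape[2]):
                    yield f"{name}[{j + 1}]", a[:, :, j]

    def rhat(self) -> dict:
        return {label: split_rhat(a) for label, a in self.iter_scalars()}

    def max_rhat(self) -> float:
        return max(self.rhat().values())

    def summary(self) -> pd.DataFrame:
        rows = []
        for label, a in self.iter_scalars():
            flat = a.ravel()
            q = np.percentile(flat, [2.5, 50, 97.5])
            rows.append(
                {
                    "parameter": label,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    "q2.5": q[0],
                    "q50": q[1],
                    "q97.5": q[2],
                    "rhat": split_rhat(a),
                }
            )
        return pd.DataFrame(rows)

    def subsample(self, n: int, rng: np.random.Generator) -> dict:
        """Dict of pooled draws thinned to ``n`` joint samples (consistent rows)."""
        total = self.n_chains * self.n_kept
        idx = (
            rng.choice(total, size=n, replace=False)
            if n < total
            else np.arange(total)
        )
        return {name: self.pooled(name)[idx] for name in self.draws}

    # -- text persistence (chain, iteration, parameter, value) ---------------

    def write_csv(self, path, thin: int = 1) -> None:
        frames = []
        for label, a in self.iter_scalars():
            a = a[:, ::thin]
            c, k = a.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(1, c + 1), k),
                        "iteration": np.tile(np.arange(1, k + 1), c),
                        "parameter": label,
                        "value": a.ravel(),
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "PosteriorDraws":
        df = pd.read_csv(path)
        flat = {}
        for label, g in df.groupby("parameter", sort=False):
            c = g["chain"].nunique()
            flat[label] = g["value"].to_numpy().reshape(c, -1)
        draws: dict = {}
        blocks: dict = {}
        for label, a in flat.items():
            if label.endswith("]") and "[" in label:
                base, idx = label[:-1].rsplit("[", 1)
                blocks.setdefault(base, []).append((int(idx), a))
            else:
                draws[label] = a
        for base, parts in blocks.items():
            parts.sort()
            draws[base] = np.stack([a for _, a in parts], axis=2)
        return cls(draws)


@dataclass
class PredictiveSeries:
    """Posterior-predictive draws of a forecast or imputed series."""

    start_year: int
    draws: np.ndarray  # (n_draws, n_steps) or (n_draws, n_cells)
    index: np.ndarray | None = None  # cell offsets for imputation targets
    name: str = "wt"

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, float)
        if self.draws.ndim != 2:
            raise ValueError("draws must be 2-d (draw, position)")

    @property
    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    @property
    def median(self) -> np.ndarray:
        return np.median(self.draws, axis=0)

    def interval(self, level: float = 0.95):
        a = 100 * (1 - level) / 2
        lo, hi = np.percentile(self.draws, [a, 100 - a], axis=0)
        return lo, hi

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.interval()
        df = pd.DataFrame(
            {"mean": self.mean, "median": self.median, "q2.5": lo, "q97.5": hi}
        )
        if self.index is not None:
            df.insert(0, "cell", self.index)
        return df
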