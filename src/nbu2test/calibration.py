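"""Monte-Carlo calibration of the complete-data statistic under H0.

The null distribution of the statistic depends on the sample size n and the
transform parameter s, so critical values are obtained by simulating the
statistic on unit-exponential samples (rate 1 is the conventional choice and
reproduces the published magnitudes).  Empirical quantiles use linear
interpolation between order statistics (numpy's default, "type 7").
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import delta_hat_rows

__all__ = ["CriticalTable", "simulate_null", "critical_point", "build_table"]

DEFAULT_LEVELS = (0.95, 0.98, 0.99)


def _check_args(n: int, n_reps: int) -> None:
    if n < 2:
        raise ValueError("need sample size n >= 2")
    if n_reps < 100:
        raise ValueError("need at least 100 Monte-Carlo replicates")


def simulate_null(n: int, s: float, n_reps: int = 10_000, seed: int | None = None) -> np.ndarray:
    """Draw the null distribution: the statistic on n_reps Exp(1) samples of size n."""
    _check_args(n, n_reps)
    rng = np.random.default_rng(seed)
    X = rng.exponential(size=(n_reps, n))
    return delta_hat_rows(X, s)


def critical_point(
    n: int, s: float, alpha: float = 0.05, n_reps: int = 10_000, seed: int | None = None
) -> float:
    """Upper-alpha Monte-Carlo critical value of the null statistic."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return float(np.quantile(simulate_null(n, s, n_reps, seed), 1 - alpha))


@dataclass(frozen=True)
class CriticalTable:
    """Upper percentile points of the null statistic over a grid of n.

    ``values[i, j]`` is the ``levels[j]`` upper percentile point at sample
    size ``sample_sizes[i]``.
    """

    s: float
    sample_sizes: tuple[int, ...]
    levels: tuple[float, ...]
    values: np.ndarray
    n_reps: int
    seed: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_sizes), len(self.levels)):
            raise ValueError("values shape must be (len(sample_sizes), len(levels))")
        if np.any(v < 0):
            raise ValueError("percentile points must be non-negative")
        if np.any(np.diff(v, axis=1) < 0):
            raise ValueError("within a row, points must be non-decreasing in the level")

    def lookup(self, n: int, level: float) -> float:
        """Critical value at (n, level); linear interpolation in n off the grid."""
        try:
            j = self.levels.index(level)
        except ValueError:
            raise KeyError(f"level {level} not tabulated (have {self.levels})") from None
        ns = np.asarray(self.sample_sizes, dtype=float)
        if not ns.min() <= n <= ns.max():
            raise ValueError(f"n={n} outside tabulated range [{ns.min():g}, {ns.max():g}]")
        return float(np.interp(n, ns, self.values[:, j]))

    def to_tsv(self) -> str:
        header = "n\t" + "\t".join(f"q{round(100 * lv)}" for lv in self.levels)
        lines = [header]
        for i, n in enumerate(self.sample_sizes):
            lines.append(str(n) + "\t" + "\t".join(f"{v:.6g}" for v in self.values[i]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(
        cls,
        text: str,
        s: float,
        n_reps: int = 0,
        seed: int | None = None,
    ) -> "CriticalTable":
        rows = [ln.split("\t") for ln in io.StringIO(text).read().splitlines() if ln.strip()]
        header = rows[0]
        levels = tuple(float(h.lstrip("q")) / 100 for h in header[1:])
        ns = tuple(int(r[0]) for r in rows[1:])
        vals = np.array([[float(x) for x in r[1:]] for r in rows[1:]])
        return cls(s=s, sample_sizes=ns, levels=levels, values=vals, n_reps=n_reps, seed=seed)


def build_table(
    s: float,
    sample_sizes: Sequence[int],
    levels: Sequence[float] = DEFAULT_LEVELS,
    n_reps: int = 10_000,
    seed: int | None = None,
) -> CriticalTable:
    """Tabulate upper percentile points over a grid of sample sizes.

    One independent child stream per sample size, spawned deterministically
    from the master seed so the table is reproducible row by row.
    """
    sizes = tuple(int(n) for n in sample_sizes)
    levels = tuple(float(lv) for lv in levels)
    if sorted(levels) != list(levels):
        raise ValueError("levels must be increasing")
    child_seeds = np.random.SeedSequence(seed).spawn(len(sizes))
    values = np.empty((len(sizes), len(levels)))
    for i, (n, ss) in enumerate(zip(sizes, child_seeds)):
        draws = delta_hat_rows(
            np.random.default_rng(ss).exponential(size=(n_reps, n)), s
        )
        values[i] = np.quantile(draws, levels)
    return CriticalTable(
        s=s, sample_sizes=sizes, levels=levels, values=values, n_reps=n_reps, seed=seed
    )
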