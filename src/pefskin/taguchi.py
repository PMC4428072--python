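"""L25 orthogonal-array dose ranking by Taguchi signal-to-noise ratios.

The treatment screen varies three pulse parameters (voltage, pulse
length, pulse number) over five levels each in 25 runs of the L25(5^k)
orthogonal array.  Each run's replicate responses (collagen content
ratio, larger is better) are collapsed to a signal-to-noise ratio
S/N = -10 log10(mean(1/y^2)); per-factor level means of S/N, their
range Delta = max - min, and the resulting ranks (1 = most influential,
ties share the smaller rank) quantify each parameter's leverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TaguchiDesign",
    "SNRankResult",
    "l25_design",
    "sn_larger_is_better",
    "sn_smaller_is_better",
    "sn_nominal_is_best",
    "rank_factors",
    "analyze_study",
]


@dataclass(frozen=True)
class TaguchiDesign:
    """Design matrix: factor names, level values, and per-run level indices."""

    factors: tuple[str, ...]
    levels: np.ndarray  # (n_factors, 5) level values
    runs: np.ndarray  # (25, n_factors) level indices 0..4

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    def level_values(self) -> pd.DataFrame:
        """Per-run physical level values."""
        data = {
            f: self.levels[k][self.runs[:, k]] for k, f in enumerate(self.factors)
        }
        return pd.DataFrame(data, index=pd.RangeIndex(self.n_runs, name="run"))

    def is_orthogonal(self) -> bool:
        """Every ordered level pair occurs exactly once for every factor pair."""
        nf = self.runs.shape[1]
        for a in range(nf):
            for b in range(a + 1, nf):
                counts = np.zeros((5, 5), dtype=int)
                np.add.at(counts, (self.runs[:, a], self.runs[:, b]), 1)
                if not np.all(counts == 1):
                    return False
        return True


def l25_design(
    levels: dict[str, list[float]] | None = None,
) -> TaguchiDesign:
    """Standard L25(5^k) array assigned to the given factors.

    ``levels`` maps factor name to its five level values; defaults to
    the screened pulse parameters (voltage 100-500 V, pulse length
    10-90 us, pulse number 200-1000).  Columns come from the classical
    Latin-square construction: with run index r = 5a + b, the columns
    are a, b, (a+b) mod 5, (a+2b) mod 5, ... (mutually orthogonal).
    """
    if levels is None:
        levels = {
            "voltage": [100, 200, 300, 400, 500],
            "pulse_length": [10e-6, 30e-6, 50e-6, 70e-6, 90e-6],
            "n_pulses": [200, 400, 600, 800, 1000],
        }
    factors = tuple(levels.keys())
    if len(factors) > 6:
        raise ValueError("L25 supports at most 6 factors")
    lv = np.asarray([levels[f] for f in factors], dtype=float)
    if lv.shape[1] != 5:
        raise ValueError("each factor needs exactly 5 levels")
    for k, f in enumerate(factors):
        if len(np.unique(lv[k])) != 5:
            raise ValueError(f"duplicate levels within factor {f!r}")
    a, b = np.divmod(np.arange(25), 5)
    cols = [a, b] + [(a + m * b) % 5 for m in range(1, 5)]
    runs = np.stack(cols[: len(factors)], axis=1)
    return TaguchiDesign(factors=factors, levels=lv, runs=runs)


def sn_larger_is_better(y) -> float:
    """S/N = -10 log10(mean(1/y^2)), in dB; requires y > 0."""
    y = np.asarray(y, dtype=float)
    if y.size == 0 or np.any(y <= 0):
        raise ValueError("larger-is-better S/N requires positive responses")
    return float(-10.0 * np.log10(np.mean(1.0 / y**2)))


def sn_smaller_is_better(y) -> float:
    """S/N = -10 log10(mean(y^2)), in dB."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty response set")
    return float(-10.0 * np.log10(np.mean(y**2)))


def sn_nominal_is_best(y) -> float:
    """S/N = 10 log10(ybar^2 / s^2), in dB; needs >= 2 replicates."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("nominal-is-best S/N needs replicates")
    s2 = np.var(y, ddof=1)
    if s2 == 0:
        raise ValueError("zero variance")
    return float(10.0 * np.log10(np.mean(y) ** 2 / s2))


@dataclass
class SNRankResult:
    """Per-run S/N, per-factor level means, Delta ranges, and ranks."""

    factors: tuple[str, ...]
    sn_per_run: np.ndarray | None
    level_means: np.ndarray  # (n_factors, 5) dB
    delta: np.ndarray  # (n_factors,) dB
    rank: np.ndarray  # (n_factors,) 1 = largest delta; ties share smaller rank

    def table(self) -> pd.DataFrame:
        """Level-mean table in the layout of the published rankings."""
        df = pd.DataFrame(
            self.level_means.T,
            columns=list(self.factors),
            index=pd.Index(range(1, 6), name="level"),
        )
        df.loc["delta"] = self.delta
        df.loc["rank"] = self.rank
        return df


def _competition_ranks(delta: np.ndarray) -> np.ndarray:
    """Rank 1 = largest; tied values share the smallest rank of the group."""
    delta = np.asarray(delta, dtype=float)
    return np.array([1 + int(np.sum(delta > d)) for d in delta])


def rank_factors(
    level_means, factors: tuple[str, ...] | None = None, sn_per_run=None
) -> SNRankResult:
    """Delta (level-mean range) and influence rank per factor.

    ``level_means`` is (n_factors, 5) mean S/N values in dB.  Delta is
    max - min over levels; rank 1 goes to the largest Delta, with tied
    factors sharing the smaller rank.
    """
    lm = np.asarray(level_means, dtype=float)
    if lm.ndim != 2 or lm.shape[1] != 5:
        raise ValueError("expected (n_factors, 5) level means")
    if factors is None:
        factors = tuple(f"factor{k + 1}" for k in range(lm.shape[0]))
    delta = lm.max(axis=1) - lm.min(axis=1)
    return SNRankResult(
        factors=tuple(factors),
        sn_per_run=None if sn_per_run is None else np.asarray(sn_per_run),
        level_means=lm,
        delta=delta,
        rank=_competition_ranks(delta),
    )


def analyze_study(
    design: TaguchiDesign, responses: pd.DataFrame, sn=sn_larger_is_better
) -> SNRankResult:
    """Full analysis: per-run S/N -> per-factor level means -> Delta -> rank.

    ``responses`` has columns ``run`` (0-based) and ``y`` (one row per
    replicate).  Every design run must be present.
    """
    if not {"run", "y"} <= set(responses.columns):
        raise ValueError("responses need columns 'run' and 'y'")
    present = set(responses["run"].unique())
    if present != set(range(design.n_runs)):
        raise ValueError("responses do not cover the 25 design runs exactly")
    sn_per_run = (
        responses.groupby("run")["y"].apply(lambda g: sn(g.to_numpy())).to_numpy()
    )
    nf = len(design.factors)
    level_means = np.empty((nf, 5))
    for k in range(nf):
        for lev in range(5):
            level_means[k, lev] = sn_per_run[design.runs[:, k] == lev].mean()
    res = rank_factors(level_means, factors=design.factors)
    res.sn_per_run = sn_per_run
    return res
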