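"""Two-genotype Wright-Fisher competition and selection-coefficient inference.

Competitive fitness assays propagate a 50:50 mix of a GFP-marked focal
genotype and a competitor for ~11 generations at an effective census of
~1000 worms per transfer, then census the end proportion by flow sorting
(COPAS). The model is a haploid Wright-Fisher process with viability
selection: if the focal genotype has relative fitness 1+s versus 1, the
post-selection expected proportion is

    p' = p(1+s) / (p(1+s) + (1-p))

and the next generation's focal count is Binomial(N, p'). The N -> infinity
limit is the logistic trajectory p_t = p0 (1+s)^t / (p0 (1+s)^t + 1 - p0),
whose exact inversion gives the point estimate of s from an observed final
proportion; the interval around it is the set of s values whose simulated
final-proportion distribution at the experiment's N and duration places the
observation within its central 95%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CompetitionConfig",
    "GateThresholds",
    "CompetitionResult",
    "SelectionEstimate",
    "gate_copas",
    "simulate_competition",
    "closed_form_trajectory",
    "infer_selection",
    "relative_fitness",
]


@dataclass(frozen=True)
class CompetitionConfig:
    """Wright-Fisher competition setup.

    ``N`` is the per-generation census at each plate transfer (default
    1000) and ``generations`` the number of transfers-worth of growth
    (default 11, the upper end of the ~10-11 generations a competition
    runs). ``s`` is the focal genotype's selection coefficient.
    """

    s: float
    N: int = 1000
    generations: int = 11
    p0: float = 0.5
    replicates: int = 1
    seed: int | None = None
    bottleneck: int | None = None  # optional second bottleneck per transfer

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must be in [0, 1]")
        if self.s <= -1.0:
            raise ValueError("s must exceed -1")
        if self.generations < 0 or self.replicates < 1:
            raise ValueError("generations must be >= 0 and replicates >= 1")


@dataclass(frozen=True)
class GateThresholds:
    """COPAS green-fluorescence gates: > high is GFP(+), < low is GFP(-)."""

    high: float = 50_000.0
    low: float = 20_000.0

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("low threshold must be below high threshold")


@dataclass
class CompetitionResult:
    trajectories: np.ndarray   # (replicates, generations + 1) focal proportions
    config: CompetitionConfig

    def __post_init__(self) -> None:
        if ((self.trajectories < 0) | (self.trajectories > 1)).any():
            raise ValueError("proportions must lie in [0, 1]")

    @property
    def final_proportions(self) -> np.ndarray:
        return self.trajectories[:, -1]

    @property
    def mean_final(self) -> float:
        return float(self.final_proportions.mean())


def gate_copas(events: pd.DataFrame, thr: GateThresholds = GateThresholds()):
    """Partition COPAS events by fluorescence gates.

    Returns (n_pos, n_neg, n_ambiguous, proportion_pos); the proportion is
    computed over unambiguous events only. Assays report at most a few
    ambiguous worms per thousand, so their exclusion is immaterial.
    """
    if len(events) == 0:
        raise ValueError("need at least one event")
    h = events["green_peak_height"].to_numpy(dtype=float)
    n_pos = int((h > thr.high).sum())
    n_neg = int((h < thr.low).sum())
    n_amb = len(h) - n_pos - n_neg
    if n_pos + n_neg == 0:
        raise ValueError("all events ambiguous: proportion undefined")
    return n_pos, n_neg, n_amb, n_pos / (n_pos + n_neg)


def simulate_competition(
    cfg: CompetitionConfig,
    rng: np.random.Generator | None = None,
    deterministic: bool = False,
) -> CompetitionResult:
    """Run replicate Wright-Fisher competitions.

    ``deterministic=True`` drops the binomial resampling (the infinite-N
    limit), leaving the logistic mean trajectory. States 0 and 1 are
    absorbing. An optional ``cfg.bottleneck`` applies a second, smaller
    binomial resampling per transfer, mimicking the chunk transfer.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    R, G = cfg.replicates, cfg.generations
    traj = np.empty((R, G + 1), dtype=float)
    p = np.full(R, cfg.p0, dtype=float)
    traj[:, 0] = p
    for t in range(1, G + 1):
        w = p * (1.0 + cfg.s)
        denom = w + (1.0 - p)
        p_sel = np.where(denom > 0, w / denom, 0.0)
        if deterministic:
            p = p_sel
        else:
            if cfg.bottleneck is not None:
                k = rng.binomial(cfg.bottleneck, p_sel)
                p_sel = k / cfg.bottleneck
            p = rng.binomial(cfg.N, p_sel) / cfg.N
        traj[:, t] = p
    return CompetitionResult(trajectories=traj, config=cfg)


def closed_form_trajectory(s: float, p0: float, t: float) -> float:
    """Deterministic (infinite-N) focal proportion after t generations."""
    if s <= -1.0:
        raise ValueError("s must exceed -1")
    if p0 in (0.0, 1.0):
        return float(p0)
    num = p0 * (1.0 + s) ** t
    return float(num / (num + (1.0 - p0)))


@dataclass(frozen=True)
class SelectionEstimate:
    s_hat: float               # NaN when p_final is absorbed at 0 or 1
    interval: tuple[float, float]
    p_final: float
    one_sided: bool = False


def invert_trajectory(p_final: float, p0: float, t: float) -> float:
    """Exact inverse of the logistic trajectory: the s reaching p_final in t."""
    if not 0.0 < p_final < 1.0 or not 0.0 < p0 < 1.0:
        raise ValueError("inversion requires interior proportions")
    odds_ratio = (p_final * (1.0 - p0)) / ((1.0 - p_final) * p0)
    return float(odds_ratio ** (1.0 / t) - 1.0)


def infer_selection(
    p_final: float,
    p0: float = 0.5,
    generations: int = 11,
    N: int = 1000,
    replicates: int = 1000,
    grid: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    level: float = 0.95,
) -> SelectionEstimate:
    """Selection coefficient consistent with an observed final proportion.

    The point estimate is the closed-form inversion; the interval is the
    range of grid values of s whose simulated final-proportion distribution
    (at the experiment's N, duration and p0) contains ``p_final`` within
    its central ``level`` mass. Observed proportions of exactly 0 or 1 are
    absorbed states and admit only a one-sided bound.
    """
    if rng is None:
        rng = np.random.default_rng()
    one_sided = p_final in (0.0, 1.0)
    s_hat = np.nan if one_sided else invert_trajectory(p_final, p0, generations)

    if grid is None:
        center = s_hat if not np.isnan(s_hat) else (-0.5 if p_final == 0.0 else 1.0)
        # ~4 sd of the sampling noise mapped into s units, floored at 0.1
        half = max(0.1, 10.0 / np.sqrt(N * generations))
        lo = max(center - half, -0.95)
        grid = np.arange(lo, center + half + 1e-9, 0.005)

    alpha = (1.0 - level) / 2.0
    accepted = []
    for s in grid:
        cfg = CompetitionConfig(
            s=float(s), N=N, generations=generations, p0=p0, replicates=replicates
        )
        finals = simulate_competition(cfg, rng).final_proportions
        q_lo, q_hi = np.quantile(finals, [alpha, 1.0 - alpha])
        if q_lo <= p_final <= q_hi:
            accepted.append(float(s))
    if not accepted:
        accepted = [s_hat] if not np.isnan(s_hat) else [float(grid[0])]
    # the acceptance boundary lies between the last accepted and first
    # rejected grid point; extend by half a step to undo discretization bias
    half_step = float(np.diff(grid).mean() / 2.0) if len(grid) > 1 else 0.0
    return SelectionEstimate(
        s_hat=float(s_hat),
        interval=(min(accepted) - half_step, max(accepted) + half_step),
        p_final=float(p_final),
        one_sided=one_sided,
    )


def relative_fitness(
    test: SelectionEstimate, control: SelectionEstimate
) -> SelectionEstimate:
    """Difference in inferred s between a test and a control competition.

    The interval combines the two grids independently:
    [lo_t - hi_c, hi_t - lo_c].
    """
    diff = test.s_hat - control.s_hat
    lo = test.interval[0] - control.interval[1]
    hi = test.interval[1] - control.interval[0]
    return SelectionEstimate(
        s_hat=float(diff),
        interval=(float(lo), float(hi)),
        p_final=np.nan,
        one_sided=test.one_sided or control.one_sided,
    )
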