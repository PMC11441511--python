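"""Deterministic two-clone selection model for growth-rate trajectories.

A rare focal clone with relative per-generation fitness ``w*`` competes
against a resident background in serial-passage culture.  Writing ``p_t``
for the focal-clone frequency after ``t`` generations and ``q_t = 1 - p_t``,
deterministic selection theory gives

    p_t / q_t = (p_0 / q_0) * w***t

so ``p_t = p_0 w***t / (p_0 w***t + q_0)``.  The observable is the mean
population growth rate (doublings/day), modelled as the frequency-weighted
mean of the clone growth rates,

    GR(t) = eta_anc + (eta_sel - eta_anc) * p_t,

which rises sigmoidally from the ancestral rate ``eta_anc`` toward the
selected-clone rate ``eta_sel`` as the sweep proceeds.  ``SelectionModel``
fits ``(p_0, w*, eta_anc, eta_sel)`` to a measured growth-rate-versus-
generation trajectory by bounded nonlinear least squares.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "SelectionParams",
    "GrowthTrajectory",
    "SelectionModel",
    "SelectionResults",
    "clone_frequency",
    "predicted_growth_rate",
    "time_to_frequency",
    "growth_rate_from_counts",
    "days_to_generations",
]

# Default bounds for the free parameters, in fit order (p0, w*, eta_anc, eta_sel).
P0_BOUNDS = (1e-6, 1.0 - 1e-6)
W_BOUNDS = (1e-3, 1e3)
ETA_BOUNDS = (-10.0, 10.0)

#: 75 days of culture correspond to ~40 cell generations.
DAYS_PER_GENERATION = 75.0 / 40.0


@dataclass(frozen=True)
class SelectionParams:
    """Parameters of the two-clone selection model.

    Parameters
    ----------
    p0 : float
        Initial focal-clone frequency, in (0, 1).
    w_star : float
        Relative fitness of the focal clone: the ratio of per-generation
        multiplication factors of focal vs background clones.  ``w_star > 1``
        drives a selective sweep.
    eta_anc : float
        Growth rate of the non-focal background, doublings/day.
    eta_sel : float
        Growth rate of the focal clone, doublings/day.
    """

    p0: float
    w_star: float
    eta_anc: float = 0.0
    eta_sel: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p0", "w_star", "eta_anc", "eta_sel"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError(f"p0 must lie strictly in (0, 1), got {self.p0}")
        if self.w_star <= 0.0:
            raise ValueError(f"w_star must be positive, got {self.w_star}")

    @property
    def q0(self) -> float:
        """Initial frequency of the competing clone(s), 1 - p0."""
        return 1.0 - self.p0


def clone_frequency(params: SelectionParams, t) -> float | np.ndarray:
    """Focal-clone frequency after ``t`` generations (closed form).

    Evaluates ``p_t = p0 w*^t / (p0 w*^t + 1 - p0)``, computed as
    ``1 / (1 + (q0/p0) w*^-t)`` for numerical stability at large ``t``.
    ``t`` may be a scalar or array and may be real-valued.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("generation index must be finite")
    if np.any(t < 0):
        raise ValueError("generation index must be non-negative")
    odds0 = params.q0 / params.p0
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + odds0 * params.w_star ** (-t))
    return float(p) if p.ndim == 0 else p


def predicted_growth_rate(params: SelectionParams, t) -> float | np.ndarray:
    """Population growth rate at generation ``t`` (doublings/day).

    Frequency-weighted mean of the clone growth rates:
    ``GR(t) = eta_anc + (eta_sel - eta_anc) * p_t``.
    """
    p = clone_frequency(params, t)
    return params.eta_anc + (params.eta_sel - params.eta_anc) * p


def time_to_frequency(params: SelectionParams, threshold: float) -> Optional[int]:
    """Smallest integer generation ``t`` with ``p_t >= threshold``.

    Solved in closed form from ``w*^t = (threshold/(1-threshold)) * q0/p0``
    and verified against :func:`clone_frequency`.  Returns ``None`` when the
    threshold is never reached (``w* <= 1`` and ``threshold > p0``).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if params.p0 >= threshold:
        return 0
    if params.w_star <= 1.0:
        return None  # frequency non-increasing; threshold unreachable
    target_odds = threshold / (1.0 - threshold) * params.q0 / params.p0
    t = math.ceil(math.log(target_odds) / math.log(params.w_star))
    t = max(t, 0)
    # guard the ceil against floating-point error at the boundary
    while t > 0 and clone_frequency(params, t - 1) >= threshold:
        t -= 1
    while clone_frequency(params, t) < threshold:
        t += 1
    return t


def growth_rate_from_counts(n0: float, nf: float, t_days: float) -> float:
    """Growth rate eta (doublings/day) from cell counts: ``N_f = N_0 2^(eta t)``."""
    if n0 <= 0 or nf <= 0:
        raise ValueError("cell counts must be positive")
    if t_days <= 0:
        raise ValueError("elapsed time must be positive")
    return math.log2(nf / n0) / t_days


def days_to_generations(days, days_per_generation: float = DAYS_PER_GENERATION):
    """Convert days of culture to cell generations (default 1.875 d/generation)."""
    if days_per_generation <= 0:
        raise ValueError("days_per_generation must be positive")
    return np.asarray(days, dtype=float) / days_per_generation


class GrowthTrajectory:
    """Replicate-averaged population growth rate indexed by generation.

    Parameters
    ----------
    t : array-like
        Generation indices, strictly increasing, non-negative.
    gr : array-like
        Mean growth rate per generation, doublings/day.
    sem : array-like, optional
        Standard error of the mean per point (NaN when unavailable).
    n : array-like, optional
        Replicate count per point (default 1).
    """

    def __init__(self, t, gr, sem=None, n=None):
        self.t = np.asarray(t, dtype=float)
        self.gr = np.asarray(gr, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.gr.shape:
            raise ValueError("t and gr must be 1-d arrays of equal length")
        if np.any(self.t < 0) or np.any(np.diff(self.t) <= 0):
            raise ValueError("generation indices must be non-negative and strictly increasing")
        if not np.all(np.isfinite(self.gr)):
            raise ValueError("growth rates must be finite")
        self.sem = (
            np.full_like(self.gr, np.nan) if sem is None else np.asarray(sem, dtype=float)
        )
        self.n = np.ones_like(self.gr, dtype=int) if n is None else np.asarray(n, dtype=int)
        if np.any(self.n < 1):
            raise ValueError("replicate counts must be >= 1")

    def __len__(self) -> int:
        return len(self.t)

    @classmethod
    def from_replicates(cls, df: pd.DataFrame) -> "GrowthTrajectory":
        """Aggregate a replicate-level table to mean +/- SEM per generation.

        ``df`` needs columns ``replicate, generation, growth_rate_per_day``.
        """
        required = {"replicate", "generation", "growth_rate_per_day"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        g = df.groupby("generation")["growth_rate_per_day"]
        agg = g.agg(["mean", "sem", "count"]).sort_index()
        return cls(agg.index.to_numpy(), agg["mean"].to_numpy(),
                   agg["sem"].to_numpy(), agg["count"].to_numpy())

    @classmethod
    def from_tsv(cls, path) -> "GrowthTrajectory":
        """Read a replicate-level trajectory TSV and aggregate it."""
        return cls.from_replicates(pd.read_csv(path, sep="\t"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"generation": self.t, "growth_rate_per_day": self.gr, "sem": self.sem, "n": self.n}
        )


@dataclass
class SelectionFit:
    """Raw optimisation outcome for one start (internal)."""

    x: np.ndarray
    rss: float
    success: bool


class SelectionModel:
    """Deterministic selection model for a growth-rate trajectory.

    Parameters
    ----------
    trajectory : GrowthTrajectory
        The observed mean growth rate per generation.
    fix_eta_anc, fix_eta_sel : float, optional
        Pin the endpoint growth rates to supplied values, reducing the fit to
        the two selection parameters (p0, w*).
    weights : {"none", "sem"}
        Residual weighting; ``"sem"`` scales residuals by 1/SEM where SEM is
        finite and positive.

    Examples
    --------
    >>> params = SelectionParams(0.0103, 2.23, 0.25, 0.5)
    >>> t = np.arange(41)
    >>> traj = GrowthTrajectory(t, predicted_growth_rate(params, t))
    >>> res = SelectionModel(traj).fit()
    >>> round(res.params.w_star, 2)
    2.23
    """

    #: trajectories flatter than this range (doublings/day) carry no selection signal
    FLAT_TOL = 1e-6

    def __init__(self, trajectory: GrowthTrajectory,
                 fix_eta_anc: Optional[float] = None,
                 fix_eta_sel: Optional[float] = None,
                 weights: str = "none"):
        if len(trajectory) < 4:
            raise ValueError("need >= 4 trajectory points to fit 4 parameters")
        if weights not in ("none", "sem"):
            raise ValueError("weights must be 'none' or 'sem'")
        self.trajectory = trajectory
        self.fix_eta_anc = fix_eta_anc
        self.fix_eta_sel = fix_eta_sel
        self._w = np.ones_like(trajectory.gr)
        if weights == "sem":
            ok = np.isfinite(trajectory.sem) & (trajectory.sem > 0)
            self._w = np.where(ok, 1.0 / np.where(ok, trajectory.sem, 1.0), 1.0)

    # -- parameter packing ------------------------------------------------

    def _unpack(self, x: np.ndarray) -> SelectionParams:
        p0, w = x[0], x[1]
        i = 2
        if self.fix_eta_anc is None:
            ea, i = x[i], i + 1
        else:
            ea = self.fix_eta_anc
        es = x[i] if self.fix_eta_sel is None else self.fix_eta_sel
        return SelectionParams(p0, w, ea, es)

    def _bounds(self):
        lo = [P0_BOUNDS[0], W_BOUNDS[0]]
        hi = [P0_BOUNDS[1], W_BOUNDS[1]]
        if self.fix_eta_anc is None:
            lo.append(ETA_BOUNDS[0])
            hi.append(ETA_BOUNDS[1])
        if self.fix_eta_sel is None:
            lo.append(ETA_BOUNDS[0])
            hi.append(ETA_BOUNDS[1])
        return np.array(lo), np.array(hi)

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        params = self._unpack(x)
        return (predicted_growth_rate(params, self.trajectory.t) - self.trajectory.gr) * self._w

    def _default_start(self) -> np.ndarray:
        gr = self.trajectory.gr
        start = [0.01, 2.0]
        if self.fix_eta_anc is None:
            start.append(float(gr[0]))
        if self.fix_eta_sel is None:
            start.append(float(gr[-1]))
        return np.array(start)

    def _random_start(self, rng: np.random.Generator) -> np.ndarray:
        gr = self.trajectory.gr
        spread = max(float(gr.max() - gr.min()), 0.05)
        start = [10 ** rng.uniform(-4, -0.3), 10 ** rng.uniform(-0.3, 1.0)]
        if self.fix_eta_anc is None:
            start.append(float(gr[0]) + rng.normal(0, 0.3 * spread))
        if self.fix_eta_sel is None:
            start.append(float(gr[-1]) + rng.normal(0, 0.3 * spread))
        return np.array(start)

    # -- fitting -----------------------------------------------------------

    def fit(self, start: Optional[Sequence[float]] = None, n_restarts: int = 10,
            seed: int = 0, bootstrap: int = 0) -> "SelectionResults":
        """Fit by bounded least squares with seeded multi-start.

        Parameters
        ----------
        start : sequence, optional
            Initial guess in fit order (p0, w*, [eta_anc], [eta_sel]); the
            default is a heuristic built from the trajectory endpoints.
        n_restarts : int
            Additional random restarts to escape the p0-w* ridge.
        seed : int
            Seed for restart sampling (and the bootstrap).
        bootstrap : int
            If > 0, parametric bootstrap draws for percentile confidence
            intervals; requires finite SEMs on the trajectory.
        """
        rng = np.random.default_rng(seed)
        lo, hi = self._bounds()
        starts = [np.clip(np.asarray(start if start is not None else self._default_start(),
                                     dtype=float), lo, hi)]
        starts += [np.clip(self._random_start(rng), lo, hi) for _ in range(n_restarts)]

        best: Optional[SelectionFit] = None
        for x0 in starts:
            sol = least_squares(self._residuals, x0, bounds=(lo, hi),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best.rss - 1e-15:
                best = SelectionFit(sol.x, rss, bool(sol.success))

        assert best is not None
        params = self._unpack(best.x)
        flat = float(self.trajectory.gr.max() - self.trajectory.gr.min()) < self.FLAT_TOL
        unident = flat or abs(params.eta_sel - params.eta_anc) < self.FLAT_TOL
        if flat:
            # no selection signal: report equal endpoint rates, p0 meaningless
            mean_gr = float(self.trajectory.gr.mean())
            params = dataclasses.replace(params, eta_anc=mean_gr, eta_sel=mean_gr)

        ci = None
        if bootstrap > 0:
            ci = self._bootstrap_ci(params, best.x, bootstrap, rng)
        return SelectionResults(self, params, best.rss, best.success, unident, ci)

    def _bootstrap_ci(self, params: SelectionParams, x_hat: np.ndarray,
                      n_boot: int, rng: np.random.Generator) -> dict:
        sem = self.trajectory.sem
        if not np.all(np.isfinite(sem) & (sem > 0)):
            raise ValueError("bootstrap intervals require finite positive SEMs")
        fitted = predicted_growth_rate(params, self.trajectory.t)
        lo, hi = self._bounds()
        draws = []
        base_gr = self.trajectory.gr
        try:
            for _ in range(n_boot):
                self.trajectory.gr = fitted + rng.normal(0.0, sem)
                sol = least_squares(self._residuals, x_hat, bounds=(lo, hi),
                                    xtol=1e-12, ftol=1e-12, gtol=1e-12)
                b = self._unpack(sol.x)
                draws.append((b.p0, b.w_star, b.eta_anc, b.eta_sel))
        finally:
            self.trajectory.gr = base_gr
        arr = np.array(draws)
        names = ("p0", "w_star", "eta_anc", "eta_sel")
        return {k: tuple(np.percentile(arr[:, j], [2.5, 97.5])) for j, k in enumerate(names)}


class SelectionResults:
    """Fit results: parameter estimates, fit quality and diagnostics."""

    def __init__(self, model: SelectionModel, params: SelectionParams, rss: float,
                 converged: bool, p0_unidentifiable: bool, ci: Optional[dict]):
        self.model = model
        self.params = params
        self.rss = rss
        self.converged = converged
        self.p0_unidentifiable = p0_unidentifiable
        self.ci = ci

    def predict(self, t) -> np.ndarray:
        """Model growth rate at generations ``t`` under the fitted parameters."""
        return predicted_growth_rate(self.params, t)

    def frequency(self, t) -> np.ndarray:
        """Fitted focal-clone frequency trajectory."""
        return clone_frequency(self.params, t)

    def time_to_frequency(self, threshold: float = 0.9) -> Optional[int]:
        return time_to_frequency(self.params, threshold)

    def to_dict(self) -> dict:
        d = {
            "p0": float(self.params.p0),
            "w_star": float(self.params.w_star),
            "eta_anc": float(self.params.eta_anc),
            "eta_sel": float(self.params.eta_sel),
            "rss": float(self.rss),
            "converged": bool(self.converged),
            "p0_unidentifiable": bool(self.p0_unidentifiable),
        }
        if self.ci is not None:
            d["ci"] = {k: [float(x) for x in v] for k, v in self.ci.items()}
        return d

    def summary(self) -> str:
        lines = [
            "Deterministic selection model fit",
            "=" * 46,
            f"{'initial frequency p0':<28}{self.params.p0:>12.6g}",
            f"{'relative fitness w*':<28}{self.params.w_star:>12.6g}",
            f"{'background eta (doub/day)':<28}{self.params.eta_anc:>12.6g}",
            f"{'focal eta (doub/day)':<28}{self.params.eta_sel:>12.6g}",
            "-" * 46,
            f"{'residual sum of squares':<28}{self.rss:>12.4g}",
            f"{'converged':<28}{str(self.converged):>12}",
            f"{'p0 unidentifiable':<28}{str(self.p0_unidentifiable):>12}",
        ]
        if self.ci is not None:
            lines.append("-" * 46)
            for k, (lo, hi) in self.ci.items():
                lines.append(f"{k + ' 95% CI':<28}[{lo:.4g}, {hi:.4g}]")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed trajectory with the fitted sigmoid (diagnostic figure)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        traj = self.model.trajectory
        ax.errorbar(traj.t, traj.gr, yerr=np.where(np.isfinite(traj.sem), traj.sem, 0.0),
                    fmt="o", label="observed", capsize=2)
        grid = np.linspace(traj.t[0], traj.t[-1], 200)
        ax.plot(grid, self.predict(grid), label="selection model")
        ax.set_xlabel("generation")
        ax.set_ylabel("growth rate (doublings/day)")
        ax.legend()
        return ax
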