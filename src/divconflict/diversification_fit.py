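"""Episodic (piecewise-constant) birth–death likelihood on a dated
extant-only tree, with adaptive time windows and maximum-likelihood fitting.

Model.  Speciation and extinction rates are constant within time windows
that tile [root age, 0].  Let ``E(t)`` be the probability that a lineage
alive at age ``t`` leaves no sampled descendant at the present (each extant
tip is sampled with probability ``rho``), and ``Phi(t)`` the probability
density that it leaves exactly one sampled lineage.  They satisfy

    dE/dt   = mu - (lambda + mu) E + lambda E^2,        E(0) = 1 - rho
    dPhi/dt = -(lambda + mu - 2 lambda E) Phi,          Phi(0) = rho

with piecewise-constant coefficients, solvable in closed form interval by
interval (the survival probability is stitched continuously at window
boundaries).  Writing ``T`` for the crown age and ``x_1..x_{n-2}`` for the
internal-node ages below the root, the log-likelihood of the ranked
reconstructed tree, conditioned on the crown age and on both crown lineages
leaving sampled descendants, is

    ln L = ln (n-1)!  +  sum_i [ ln lambda(x_i) + ln Phi(x_i) ]
           + 2 ln Phi(T) - 2 ln (1 - E(T))

which for ``mu = 0, rho = 1`` reduces to the classical product of
exponential waiting densities of the Yule process.

Windows.  The tree is tiled into ``min_width`` (default 5 Myr) windows
anchored at the present; scanning from the present toward the root, windows
are merged into their older neighbour until each holds at least
``min_events`` (default 50) branching events, a root-most remainder below
the threshold being absorbed into the adjacent younger window.

Fitting.  Three variants: EQUAL (one lambda, one mu for all windows),
VAR_SPEC (per-window lambda, shared mu) and VAR_EXT (shared lambda,
per-window mu), maximized with bounded quasi-Newton (L-BFGS-B) on
log-transformed rates from five deterministic starting points spanning
1e-2 to 1e1 Myr^-1, and compared by AIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from .tree_core import DatedTree, TreeError

__all__ = [
    "EQUAL",
    "VAR_SPEC",
    "VAR_EXT",
    "WindowSet",
    "EpisodicFit",
    "build_windows",
    "windows_from_boundaries",
    "episodic_bd_loglik",
    "fit_episodic_model",
]

EQUAL = "equal"
VAR_SPEC = "var-spec"
VAR_EXT = "var-ext"
_VARIANTS = (EQUAL, VAR_SPEC, VAR_EXT)

_MIN_RATE = 1e-6
_MAX_RATE = 1e2


@dataclass(frozen=True)
class WindowSet:
    """Contiguous time windows tiling [root age, 0].

    ``bounds`` descend from the root age to 0 (length ``n_windows + 1``);
    window ``i`` spans ``[bounds[i+1], bounds[i])`` — an event age equal to
    a boundary belongs to the older window.  ``events[i]`` counts the
    branching events (internal nodes excluding the root) in window ``i``.
    """

    bounds: tuple[float, ...]
    events: tuple[int, ...]

    def __post_init__(self):
        if len(self.bounds) != len(self.events) + 1:
            raise ValueError("need len(bounds) == n_windows + 1")
        b = self.bounds
        if any(b[i] <= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("bounds must be strictly decreasing")
        if abs(b[-1]) > 1e-12:
            raise ValueError("the youngest bound must be 0")

    @property
    def n_windows(self) -> int:
        return len(self.events)

    @property
    def widths(self) -> tuple[float, ...]:
        return tuple(self.bounds[i] - self.bounds[i + 1]
                     for i in range(self.n_windows))

    def window_index(self, age: float) -> int:
        """Index of the window containing ``age`` (ties go to the older
        window); 0 is the oldest window."""
        b = self.bounds
        for i in range(self.n_windows):
            if age >= b[i + 1]:
                return i
        return self.n_windows - 1


def _branching_ages(tree: DatedTree) -> np.ndarray:
    """Internal-node ages strictly below the crown (the root node itself is
    not a branching event under crown conditioning)."""
    return np.sort(np.asarray(tree.internal_ages(exclude_root=True)))


def build_windows(tree: DatedTree, min_width: float = 5.0,
                  min_events: int = 50) -> WindowSet:
    """Adaptive windows: ``min_width`` tiles anchored at the present, merged
    (younger into older) until every window holds >= ``min_events`` branching
    events; a sub-threshold root-most remainder joins the adjacent younger
    window; a tree with fewer than ``min_events`` events total yields the
    single window [root, 0]."""
    if min_width <= 0:
        raise ValueError("min_width must be positive")
    if min_events < 1:
        raise ValueError("min_events must be >= 1")
    root = tree.root_age
    events = _branching_ages(tree)
    edges = [0.0]
    while edges[-1] + min_width < root - 1e-12:
        edges.append(edges[-1] + min_width)
    edges.append(root)

    closed: list[tuple[float, float, int]] = []  # (young, old, count)
    young = edges[0]
    count = 0
    for j in range(len(edges) - 1):
        lo, hi = edges[j], edges[j + 1]
        count += int(np.searchsorted(events, hi, side="left")
                     - np.searchsorted(events, lo, side="left"))
        if count >= min_events:
            closed.append((young, hi, count))
            young = hi
            count = 0
    if young < root - 1e-12 or not closed:
        if closed:
            y, _, c = closed[-1]
            closed[-1] = (y, root, c + count)
        else:
            closed = [(0.0, root, count)]
    bounds = [root] + [w[0] for w in reversed(closed)]
    counts = [w[2] for w in reversed(closed)]
    return WindowSet(bounds=tuple(bounds), events=tuple(counts))


def windows_from_boundaries(tree: DatedTree, interior_bounds) -> WindowSet:
    """Windows with explicitly chosen interior boundary ages (descending),
    e.g. the known shift times of a simulation experiment."""
    root = tree.root_age
    bounds = [root] + [float(b) for b in interior_bounds if 0 < b < root] + [0.0]
    events = _branching_ages(tree)
    counts = []
    for i in range(len(bounds) - 1):
        hi, lo = bounds[i], bounds[i + 1]
        n = int(np.searchsorted(events, hi, side="left")
                - np.searchsorted(events, lo, side="left"))
        counts.append(n)
    # the oldest window also owns any event tied exactly with the root bound
    counts[0] += int(events.size - np.searchsorted(events, root, side="left"))
    return WindowSet(bounds=tuple(bounds), events=tuple(counts))


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _segment_step(e0: float, lam: float, mu: float, dt: float
                  ) -> tuple[float, float]:
    """Propagate (E, ln Phi) across one constant-rate span of duration
    ``dt``: returns (E(end), ln Phi(end) - ln Phi(start)).

    Closed forms: with r = lambda - mu, A = lambda (1 - E0),
    B = lambda E0 - mu,

        E(dt)              = (mu (1 - E0) + B e^{-r dt}) / (A + B e^{-r dt})
        Phi(dt) / Phi(0)   = e^{-r dt} r^2 / (A + B e^{-r dt})^2

    with the usual lambda -> mu limit.  Computed in log space so large
    ``|r| dt`` cannot overflow.
    """
    if dt == 0.0:
        return e0, 0.0
    r = lam - mu
    if abs(r) * dt < 1e-12 or abs(r) <= 1e-14 * (lam + mu):
        denom = 1.0 + lam * dt * (1.0 - e0)
        e1 = 1.0 - (1.0 - e0) / denom
        return e1, -2.0 * math.log(denom)
    a = lam * (1.0 - e0)
    b = lam * e0 - mu
    z = -r * dt
    if z < 500.0:
        x = math.exp(z)
        d = a + b * x
        e1 = (mu * (1.0 - e0) + b * x) / d
        log_abs_d = math.log(abs(d))
    else:
        # e^{-r dt} huge (strong extinction over a long span): factor it out
        xinv = math.exp(-z)
        d_scaled = a * xinv + b
        e1 = (mu * (1.0 - e0) * xinv + b) / d_scaled
        log_abs_d = z + math.log(abs(d_scaled))
    dlog_phi = z + 2.0 * math.log(abs(r)) - 2.0 * log_abs_d
    return e1, dlog_phi


def episodic_bd_loglik(tree: DatedTree, windows: WindowSet, lambda_vec,
                       mu_vec, rho: float = 1.0) -> float:
    """Log-likelihood of a reconstructed extant tree under the episodic
    birth–death process, conditioned on the crown age and survival of both
    crown lineages, with extant sampling probability ``rho``."""
    lam = np.asarray(lambda_vec, dtype=float)
    mu = np.asarray(mu_vec, dtype=float)
    if lam.size != windows.n_windows or mu.size != windows.n_windows:
        raise ValueError("rate vectors must match the window count")
    if (lam < 0).any() or (mu < 0).any():
        raise ValueError("rates must be non-negative")
    if not 0.0 < rho <= 1.0:
        raise ValueError("rho must be in (0, 1]")
    root = tree.root_age
    if abs(windows.bounds[0] - root) > 1e-6:
        raise ValueError("windows do not span the tree's root age")
    ages = _branching_ages(tree)
    n = ages.size + 2  # crown-conditioned: n-2 branching events below root

    # edges ascending from the present; segment j has the rates of window
    # (n_windows - 1 - j)
    edges = np.asarray(windows.bounds[::-1])
    k = windows.n_windows
    lam_asc = lam[::-1]
    mu_asc = mu[::-1]

    e_edges = np.empty(k + 1)
    logphi_edges = np.empty(k + 1)
    e_edges[0] = 1.0 - rho
    logphi_edges[0] = math.log(rho)
    for j in range(k):
        e1, dlp = _segment_step(e_edges[j], lam_asc[j], mu_asc[j],
                                edges[j + 1] - edges[j])
        e_edges[j + 1] = e1
        logphi_edges[j + 1] = logphi_edges[j] + dlp

    total = float(gammaln(n))
    seg = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0, k - 1)
    for x, j in zip(ages, seg):
        lam_j = lam_asc[j]
        if lam_j <= 0.0:
            return -math.inf
        _, dlp = _segment_step(e_edges[j], lam_j, mu_asc[j], x - edges[j])
        total += math.log(lam_j) + logphi_edges[j] + dlp
    e_root = e_edges[k]
    if e_root >= 1.0:
        return -math.inf
    total += 2.0 * logphi_edges[k] - 2.0 * math.log1p(-e_root)
    return total


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class EpisodicFit:
    """A fitted episodic birth–death model."""

    windows: WindowSet
    lam: np.ndarray
    mu: np.ndarray
    rho: float
    loglik: float
    n_params: int
    variant: str

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def net_rates(self) -> np.ndarray:
        return self.lam - self.mu

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "older_bound": self.windows.bounds[:-1],
            "younger_bound": self.windows.bounds[1:],
            "n_events": self.windows.events,
            "lambda": self.lam,
            "mu": self.mu,
            "net_rate": self.net_rates,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.10g")


def _pack(variant: str, k: int):
    if variant == EQUAL:
        n_lam, n_mu = 1, 1
    elif variant == VAR_SPEC:
        n_lam, n_mu = k, 1
    else:
        n_lam, n_mu = 1, k

    def unpack(theta):
        lam = np.exp(theta[:n_lam])
        mu = np.exp(theta[n_lam:])
        return np.broadcast_to(lam, k) if n_lam == 1 else lam, \
            np.broadcast_to(mu, k) if n_mu == 1 else mu

    return n_lam, n_mu, unpack


def fit_episodic_model(tree: DatedTree, windows: WindowSet,
                       variant: str = VAR_SPEC, rho: float = 1.0,
                       n_starts: int = 5) -> EpisodicFit:
    """Maximum-likelihood fit of one rate variant over a window set.

    Rates are optimized on the log scale (bounds 1e-6 to 1e2 Myr^-1, so
    mu can collapse to effectively zero) from ``n_starts`` deterministic
    log-spaced starting points.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"variant must be one of {_VARIANTS}")
    k = windows.n_windows
    n_lam, n_mu, unpack = _pack(variant, k)
    n_free = n_lam + n_mu

    def objective(theta):
        lam, mu = unpack(theta)
        ll = episodic_bd_loglik(tree, windows, lam, mu, rho)
        if not math.isfinite(ll):
            return 1e12
        return -ll

    log_bounds = [(math.log(_MIN_RATE), math.log(_MAX_RATE))] * n_free
    starts = np.log(np.logspace(-2, 1, n_starts))
    best = None
    for s in starts:
        x0 = np.full(n_free, s)
        x0[n_lam:] = s + math.log(0.2)  # start with modest turnover
        res = minimize(objective, x0, method="L-BFGS-B", bounds=log_bounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not math.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(
            f"episodic fit failed to converge from all starts; best objective "
            f"{None if best is None else best.fun}")
    lam, mu = unpack(best.x)
    return EpisodicFit(windows=windows, lam=np.asarray(lam).copy(),
                       mu=np.asarray(mu).copy(), rho=rho,
                       loglik=-float(best.fun), n_params=n_free,
                       variant=variant)
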