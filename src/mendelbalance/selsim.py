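"""Population-genetic simulation of a recessive lethal under selection.

Two complementary models:

* ``simulate_drift`` — stochastic Wright-Fisher reproduction with genotype
  viabilities, to ask how far a lethal recessive can rise by drift alone in a
  finite population.

* ``balancing_recursion`` — a deterministic recursion for a closed breeding
  program where carriers of the lethal enjoy a selection-index advantage:
  each generation, truncation selection enriches carriers among the selected
  parents, random mating produces Hardy-Weinberg offspring, and homozygotes
  for the lethal are removed.  With equal carrier advantage s in both sexes
  the recursion has the stable fixed point c* = 2s / (1 + 3s) in carrier
  frequency: purging of homozygotes balances the heterozygote advantage.

``truncation_advantage`` converts an observed index shift for carriers into
the relative advantage s = P(selected | carrier)/P(selected | non-carrier) - 1
under normal index distributions and a fixed selected fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

EQUILIBRIUM_TOL = 1e-10


@dataclass
class DriftConfig:
    pop_size: int
    q0: float
    generations: int
    reps: int = 1
    fitness: tuple[float, float, float] = (1.0, 1.0, 0.0)  # wtwt, wtdel, deldel
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.q0 <= 1.0:
            raise ValueError("q0 outside [0, 1]")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if any(w < 0 for w in self.fitness):
            raise ValueError("fitness values must be >= 0")


@dataclass
class SelectionScenario:
    c0: float                      # initial carrier frequency
    s_male: float = 0.0            # relative carrier advantage among boars
    s_female: float = 0.0          # ... among gilts
    selected_fraction_male: float = 0.05
    selected_fraction_female: float = 0.25
    generations: int = 500
    index_mean: float | None = None       # optional truncation parameterization
    index_sd: float | None = None
    carrier_shift_pct: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.c0 < 1.0:
            raise ValueError("c0 outside [0, 1)")
        for f in (self.selected_fraction_male, self.selected_fraction_female):
            if not 0.0 < f <= 1.0:
                raise ValueError("selected fractions must be in (0, 1]")


@dataclass
class Trajectory:
    carrier_freq: np.ndarray
    allele_freq: np.ndarray
    equilibrium: float | None


@dataclass
class DriftEnsemble:
    allele_freq: np.ndarray   # (reps, generations + 1)
    seed: int

    def max_frequencies(self) -> np.ndarray:
        return self.allele_freq.max(axis=1)

    def fraction_exceeding(self, threshold: float) -> float:
        """Fraction of replicates whose allele frequency ever exceeds
        ``threshold``."""
        return float((self.max_frequencies() > threshold).mean())


# ---------------------------------------------------------------------------
# Wright-Fisher drift with viability selection
# ---------------------------------------------------------------------------

def simulate_drift(cfg: DriftConfig) -> DriftEnsemble:
    """Wright-Fisher ensemble with genotype viabilities.

    Each generation: Hardy-Weinberg genotype frequencies at conception,
    viability weighting, then binomial sampling of 2N gametes from the
    post-selection allele frequency.  The recorded trajectory is the allele
    frequency among conceived individuals (before viability selection).
    Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    w11, w12, w22 = cfg.fitness  # wtwt, wtdel, deldel
    two_n = 2 * cfg.pop_size
    q = np.full(cfg.reps, cfg.q0, dtype=float)
    traj = np.empty((cfg.reps, cfg.generations + 1))
    traj[:, 0] = q
    for t in range(1, cfg.generations + 1):
        p = 1.0 - q
        mean_w = p * p * w11 + 2 * p * q * w12 + q * q * w22
        with np.errstate(invalid="ignore", divide="ignore"):
            q_sel = np.where(mean_w > 0,
                             (q * q * w22 + p * q * w12) / mean_w, 0.0)
        q = rng.binomial(two_n, q_sel) / two_n
        traj[:, t] = q
    return DriftEnsemble(traj, cfg.seed)


# ---------------------------------------------------------------------------
# Truncation selection advantage
# ---------------------------------------------------------------------------

def truncation_advantage(index_mean: float,
                         index_sd: float,
                         carrier_shift_pct: float,
                         selected_fraction: float,
                         carrier_freq: float) -> float:
    """Relative selection advantage of carriers under truncation selection.

    Carrier index ~ Normal(mean*(1 + shift/100), sd); non-carrier ~
    Normal(mean, sd).  The threshold T is solved so that the population
    mixture has the target selected fraction; the advantage is
    s = P(index > T | carrier) / P(index > T | non-carrier) - 1.
    """
    if index_sd <= 0:
        raise ValueError("index_sd must be > 0")
    if not 0.0 < selected_fraction < 1.0:
        raise ValueError("selected_fraction must be in (0, 1)")
    if not 0.0 <= carrier_freq < 1.0:
        raise ValueError("carrier_freq outside [0, 1)")
    mu_c = index_mean * (1.0 + carrier_shift_pct / 100.0)
    c = carrier_freq

    def selected(t: float) -> float:
        return (c * stats.norm.sf(t, mu_c, index_sd)
                + (1 - c) * stats.norm.sf(t, index_mean, index_sd))

    lo = min(index_mean, mu_c) - 12 * index_sd
    hi = max(index_mean, mu_c) + 12 * index_sd
    if (selected(lo) - selected_fraction) * (selected(hi) - selected_fraction) > 0:
        raise ValueError("no bracket for the truncation threshold")
    t_star = optimize.brentq(lambda t: selected(t) - selected_fraction, lo, hi,
                             xtol=1e-12)
    s_c = stats.norm.sf(t_star, mu_c, index_sd)
    s_n = stats.norm.sf(t_star, index_mean, index_sd)
    return float(s_c / s_n - 1.0)


# ---------------------------------------------------------------------------
# Deterministic balancing recursion
# ---------------------------------------------------------------------------

def _advantages(scn: SelectionScenario, carrier_freq: float) -> tuple[float, float]:
    """Per-sex carrier advantages, either fixed or re-derived each generation
    from the truncation parameterization."""
    if scn.index_mean is not None:
        if scn.index_sd is None or scn.carrier_shift_pct is None:
            raise ValueError("truncation parameterization needs mean, sd and shift")
        return (
            truncation_advantage(scn.index_mean, scn.index_sd,
                                 scn.carrier_shift_pct,
                                 scn.selected_fraction_male, carrier_freq),
            truncation_advantage(scn.index_mean, scn.index_sd,
                                 scn.carrier_shift_pct,
                                 scn.selected_fraction_female, carrier_freq),
        )
    return scn.s_male, scn.s_female


def balancing_recursion(scn: SelectionScenario,
                        tol: float = EQUILIBRIUM_TOL) -> Trajectory:
    """Iterate the selection / Hardy-Weinberg / homozygote-loss cycle.

    Per generation, with live carrier frequency c (no live homozygotes):
    (i) selected-parent carrier frequency per sex
    c_sel = c(1+s)/(1 + c s); (ii) sex-averaged parental allele frequency
    q = mean(c_sel)/2; (iii) Hardy-Weinberg offspring from q; (iv) del/del
    offspring removed, giving live carrier frequency c' = 2q/(1+q).

    Equilibrium is reported when |c' - c| < ``tol``; otherwise the
    trajectory is returned with equilibrium = None.
    """
    c = scn.c0
    cs = [c]
    qs = [c / 2.0]
    equilibrium = None
    for _ in range(scn.generations):
        s_m, s_f = _advantages(scn, c)
        c_sel_m = c * (1 + s_m) / (1 + c * s_m)
        c_sel_f = c * (1 + s_f) / (1 + c * s_f)
        q = 0.5 * (c_sel_m / 2.0 + c_sel_f / 2.0)
        c_next = 2 * q / (1 + q)
        cs.append(c_next)
        qs.append(q)
        if abs(c_next - c) < tol:
            equilibrium = c_next
            c = c_next
            break
        c = c_next
    return Trajectory(np.asarray(cs), np.asarray(qs), equilibrium)


def equilibrium_carrier_freq(s: float) -> float:
    """Closed-form fixed point of the balancing recursion with equal-sex
    advantage s: c* = 2s / (1 + 3s)."""
    if s < 0:
        raise ValueError("s must be >= 0")
    return 2.0 * s / (1.0 + 3.0 * s)
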