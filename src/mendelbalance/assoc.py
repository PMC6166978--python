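"""Deregressed-EBV association with carrier status.

Estimated breeding values (EBVs) are shrunken, parent-average-contaminated
predictors, unsuitable as a regression response.  Deregression inverts the
shrinkage and strips the parent-average (PA) contribution, leaving a noisy
but unbiased record of each animal's own information; records are weighted
by the information content of the deregressed value.

The association model is a weighted single-marker animal model

    DEBV_ij = mu + R_i + a_j + e_ij,

with carrier status R as a 0/1 fixed effect, a polygenic effect a ~ N(0,
A sigma_a^2) using the pedigree numerator relationship matrix A, and
heteroscedastic residuals e ~ N(0, diag(1/w) sigma_e^2).  Variance
components come from a one-dimensional REML profile over the ratio
lambda = sigma_e^2 / sigma_a^2, made O(n) per evaluation by a single
eigendecomposition of the weighted relationship matrix.

Deregression follows the two-equation PA/individual mixed-model system: the
effective information contents Z'Z_PA and Z'Z_i are recovered from the
published reliabilities by inverting the 2x2 coefficient matrix

    C = [[Z'Z_PA + 4L, -2L], [-2L, Z'Z_i + 2L]],   L = (1-h^2)/h^2,

whose inverse diagonal must reproduce the prediction error variances
(0.5 - r2_PA) sigma_a^2 and (1 - r2) sigma_a^2.  Writing
A = (0.5 - r2_PA)/L and B = (1 - r2)/L, u = Z'Z_PA + 4L solves
A u^2 - u - 4 B L^2 = 0 and v = Z'Z_i + 2L = 4 A L^2 / (A u - 1); the
deregressed value is the individual right-hand side divided by Z'Z_i, and
r2_DEBV = Z'Z_i / (Z'Z_i + L).  The system degenerates as r2_PA -> 0.5
(a parent average can never carry more than half the additive variance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

DEBV_RELIABILITY_MIN = 0.20  # retention filter on deregressed reliability


@dataclass
class DEBVRecord:
    animal: str
    trait: str
    debv: float
    rel_debv: float
    weight: float
    retained: bool
    flagged: str = ""    # non-empty when the record could not be deregressed


@dataclass
class AssocResult:
    trait: str
    effect: float        # carrier minus non-carrier, trait units
    se: float
    p: float
    n_carrier: int
    n_noncarrier: int
    sigma_a2: float
    sigma_e2: float
    mu: float


# ---------------------------------------------------------------------------
# Garrick deregression
# ---------------------------------------------------------------------------

def _deregress_one(ebv: float, ebv_pa: float, rel: float, rel_pa: float,
                   h2: float, c: float):
    lam = (1.0 - h2) / h2
    if rel_pa >= 0.5:
        raise ValueError(f"rel_pa={rel_pa} >= 0.5: PA system degenerate")
    A = (0.5 - rel_pa) / lam
    B = (1.0 - rel) / lam
    u = (1.0 + math.sqrt(1.0 + 16.0 * A * B * lam * lam)) / (2.0 * A)
    v = 4.0 * A * lam * lam / (A * u - 1.0)
    zpz_i = max(v - 2.0 * lam, 1e-12)
    # right-hand side for the individual equation: y*_i = -2L g_pa + v g_i
    y_star = -2.0 * lam * ebv_pa + v * ebv
    debv = y_star / zpz_i
    rel_debv = zpz_i / (zpz_i + lam)
    denom = (c + (1.0 - rel_debv) / rel_debv) * h2
    w = (1.0 - h2) / denom
    return debv, rel_debv, w


def deregress(records: pd.DataFrame,
              c: float = 0.5,
              pedigree: pd.DataFrame | None = None) -> list[DEBVRecord]:
    """Deregress EBVs and compute association weights.

    ``records`` needs columns (animal, trait, ebv, rel, rel_pa, h2) and may
    carry an explicit ``ebv_pa`` column; otherwise the parent average is the
    mean of the parents' EBVs for the same trait via ``pedigree`` (0 when
    neither parent has a record, flagged).  Weight
    w = (1 - h2) / ((c + (1 - r2_debv)/r2_debv) h2); a record is retained
    when w > 0 and r2_debv > 0.20.  Records with rel <= rel_pa are flagged
    and not deregressed; rel_pa >= 0.5 raises.
    """
    have_pa = "ebv_pa" in records.columns
    parent_ebv: dict[tuple[str, str], float] = {}
    parents: dict[str, tuple] = {}
    if not have_pa and pedigree is not None:
        parents = {r.animal: (r.sire, r.dam)
                   for r in pedigree.itertuples(index=False)}
        parent_ebv = {(r.animal, r.trait): r.ebv
                      for r in records.itertuples(index=False)}
    out = []
    for r in records.itertuples(index=False):
        if r.rel <= r.rel_pa:
            out.append(DEBVRecord(r.animal, r.trait, np.nan, np.nan, 0.0,
                                  False, flagged="rel<=rel_pa"))
            continue
        flag = ""
        if have_pa:
            ebv_pa = float(getattr(r, "ebv_pa"))
        else:
            sire, dam = parents.get(r.animal, (None, None))
            vals = [parent_ebv[(p, r.trait)] for p in (sire, dam)
                    if (p, r.trait) in parent_ebv]
            ebv_pa = float(np.mean(vals)) if vals else 0.0
            if not vals:
                flag = "pa_unknown"
        debv, rel_debv, w = _deregress_one(r.ebv, ebv_pa, r.rel, r.rel_pa,
                                           r.h2, c)
        retained = (w > 0) and (rel_debv > DEBV_RELIABILITY_MIN)
        out.append(DEBVRecord(r.animal, r.trait, debv, rel_debv, w, retained,
                              flag))
    return out


# ---------------------------------------------------------------------------
# Numerator relationship matrix
# ---------------------------------------------------------------------------

def a_matrix(pedigree: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Henderson's tabular numerator relationship matrix.

    Unknown parents (NaN or absent from the table) are treated as unrelated
    founders.  Returns (A, animal order); rows follow a parents-first
    topological order of the pedigree.
    """
    from .core_io import _toposort

    order = _toposort(pedigree)
    in_ped = set(pedigree["animal"])
    order = [a for a in order if a in in_ped]
    pos = {a: i for i, a in enumerate(order)}
    sire_of, dam_of = {}, {}
    for r in pedigree.itertuples(index=False):
        sire_of[r.animal] = pos.get(r.sire) if pd.notna(r.sire) else None
        dam_of[r.animal] = pos.get(r.dam) if pd.notna(r.dam) else None
    n = len(order)
    A = np.zeros((n, n))
    for i, animal in enumerate(order):
        s, d = sire_of[animal], dam_of[animal]
        A[i, i] = 1.0 + (A[s, d] / 2.0 if s is not None and d is not None else 0.0)
        rel = np.zeros(i)
        if s is not None:
            rel += A[s, :i]
        if d is not None:
            rel += A[d, :i]
        A[i, :i] = A[:i, i] = rel / 2.0
    return A, order


# ---------------------------------------------------------------------------
# Weighted single-random-effect REML
# ---------------------------------------------------------------------------

def _reml_profile(log_lam: float, S, Xt, zt, n, p):
    """Negative REML log-likelihood profiled over sigma_a^2 at a fixed
    variance ratio lambda = sigma_e^2/sigma_a^2 (rotated coordinates)."""
    lam = np.exp(log_lam)
    d = S + lam
    Xw = Xt / d[:, None]
    xtx = Xt.T @ Xw
    beta = np.linalg.solve(xtx, Xw.T @ zt)
    resid = zt - Xt @ beta
    rss = float(resid @ (resid / d))
    sigma_a2 = rss / (n - p)
    ll = -0.5 * ((n - p) * math.log(sigma_a2) + np.log(d).sum()
                 + math.log(max(np.linalg.det(xtx / sigma_a2), 1e-300))
                 + (n - p))
    return -ll, beta, sigma_a2, xtx


def fit_association(debvs: list[DEBVRecord],
                    carrier_status: dict[str, int],
                    pedigree: pd.DataFrame,
                    trait: str | None = None,
                    sigma_a2_zero: bool = False) -> AssocResult:
    """Fit DEBV = mu + beta * carrier + a + e for one trait.

    Uses retained records only.  ``carrier_status`` maps animal -> 0/1.
    ``sigma_a2_zero`` collapses the model to weighted least squares (no
    polygenic effect), mainly for testing.

    REML maximizes the profile likelihood over log(lambda) with a bounded
    scalar search after rotating into the eigenbasis of
    W^(1/2) A W^(1/2) (W = diag(weights)); the reported effect is the
    carrier - non-carrier difference with its Wald standard error and
    two-sided normal p-value.
    """
    recs = [r for r in debvs if r.retained
            and (trait is None or r.trait == trait)
            and r.animal in carrier_status]
    if trait is None:
        traits = {r.trait for r in recs}
        if len(traits) != 1:
            raise ValueError("records span multiple traits; pass trait=")
        trait = traits.pop()
    animals = [r.animal for r in recs]
    y = np.array([r.debv for r in recs])
    w = np.array([r.weight for r in recs])
    status = np.array([carrier_status[a] for a in animals], dtype=float)
    n_car = int(status.sum())
    n_non = len(status) - n_car
    if n_car < 2 or n_non < 2:
        raise ValueError(
            f"need >= 2 animals per carrier class (carrier={n_car}, "
            f"non-carrier={n_non})")
    X = np.column_stack([np.ones(len(y)), status])
    n, p = X.shape

    if sigma_a2_zero:
        Xw = X * w[:, None]
        xtx = X.T @ Xw
        beta = np.linalg.solve(xtx, Xw.T @ y)
        resid = y - X @ beta
        sigma_e2 = float(resid @ (w * resid)) / (n - p)
        cov = np.linalg.inv(xtx) * sigma_e2
        se = math.sqrt(cov[1, 1])
        z = beta[1] / se
        return AssocResult(trait, float(beta[1]), se,
                           float(2 * stats.norm.sf(abs(z))), n_car, n_non,
                           0.0, sigma_e2, float(beta[0]))

    A_full, order = a_matrix(pedigree)
    pos = {a: i for i, a in enumerate(order)}
    missing = [a for a in animals if a not in pos]
    if missing:
        raise ValueError(f"animals missing from pedigree: {missing[:5]}")
    idx = np.array([pos[a] for a in animals])
    A = A_full[np.ix_(idx, idx)]

    sw = np.sqrt(w)
    M = (A * sw[:, None]) * sw[None, :]
    S, U = np.linalg.eigh(M)
    S = np.clip(S, 0.0, None)
    zt = U.T @ (sw * y)
    Xt = U.T @ (sw[:, None] * X)

    res = optimize.minimize_scalar(
        lambda ll: _reml_profile(ll, S, Xt, zt, n, p)[0],
        bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-8})
    _, beta, sigma_a2, xtx = _reml_profile(res.x, S, Xt, zt, n, p)
    lam = float(np.exp(res.x))
    cov = np.linalg.inv(xtx) * sigma_a2
    se = math.sqrt(cov[1, 1])
    if se <= 0 or not np.isfinite(se):
        raise ValueError("singular mixed-model equations (rank deficiency)")
    z = beta[1] / se
    return AssocResult(trait, float(beta[1]), se,
                       float(2 * stats.norm.sf(abs(z))), n_car, n_non,
                       sigma_a2, sigma_a2 * lam, float(beta[0]))


def association_table(debvs: list[DEBVRecord],
                      carrier_status: dict[str, int],
                      pedigree: pd.DataFrame) -> pd.DataFrame:
    """Run the association for every trait present; mirrors the layout of a
    per-trait results table (trait, n_noncarrier, n_carrier, P, -log10P,
    effect, se)."""
    traits = sorted({r.trait for r in debvs if r.retained})
    rows = []
    for t in traits:
        res = fit_association(debvs, carrier_status, pedigree, trait=t)
        rows.append({
            "trait": t,
            "n_noncarrier": res.n_noncarrier,
            "n_carrier": res.n_carrier,
            "P": res.p,
            "-log10P": -math.log10(max(res.p, 1e-300)),
            "effect": res.effect,
            "se": res.se,
        })
    return pd.DataFrame(rows)
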