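"""Litter-phenotype contrasts and carrier-frequency-over-time analysis.

Carrier-by-carrier (CxC) matings of a recessive lethal lose about a quarter
of conceptuses in utero; the loss surfaces as smaller litters and an excess
of mummified piglets.  This module classifies matings from parental carrier
status, contrasts litter traits between mating classes with Welch's t-test,
tests mummy excess against the breed baseline, and tracks carrier frequency
per half-year bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MUMMY_BASELINE = 0.35  # breed-average mummified piglets per litter

_CARRIER = {"wtdel", "deldel"}
_NONCARRIER = {"wtwt"}


@dataclass
class TraitContrast:
    trait: str
    mean_cxc: float
    mean_cxnc: float
    pct_difference: float  # 100 * (mean_cxc - mean_cxnc) / mean_cxnc
    t_stat: float
    p: float
    n_cxc: int
    n_cxnc: int


def classify_matings(litters: pd.DataFrame,
                     carrier_statuses: dict[str, str]) -> pd.DataFrame:
    """Classify each litter as CxC, CxNC, NCxNC or unknown from parental
    carrier status.  CxNC is symmetric in the parents (carrier boar x
    non-carrier sow and the reverse are the same class)."""
    def one(sire: str, dam: str) -> str:
        s = carrier_statuses.get(sire, "unknown")
        d = carrier_statuses.get(dam, "unknown")
        if s == "unknown" or d == "unknown":
            return "unknown"
        s_c, d_c = s in _CARRIER, d in _CARRIER
        if s_c and d_c:
            return "CxC"
        if s_c or d_c:
            return "CxNC"
        return "NCxNC"

    return pd.DataFrame({
        "litter_id": litters["litter_id"],
        "class": [one(s, d) for s, d in zip(litters["sire"], litters["dam"])],
    })


def contrast_trait(litters: pd.DataFrame,
                   classes: pd.DataFrame,
                   trait: str) -> TraitContrast:
    """Welch's unequal-variance t-test of a litter trait, CxC vs CxNC.

    ``trait`` is one of TNB/NBA/MUM (mapped to the tnb/nba/mummified columns)
    or any numeric litter column.
    """
    col = {"TNB": "tnb", "NBA": "nba", "MUM": "mummified"}.get(trait, trait)
    merged = litters.merge(classes, on="litter_id")
    cxc = merged.loc[merged["class"] == "CxC", col].to_numpy(dtype=float)
    cxnc = merged.loc[merged["class"] == "CxNC", col].to_numpy(dtype=float)
    if len(cxc) < 2 or len(cxnc) < 2:
        raise ValueError(
            f"need >= 2 litters per class, got CxC={len(cxc)}, CxNC={len(cxnc)}")
    t, p = stats.ttest_ind(cxc, cxnc, equal_var=False)
    m_cxc, m_cxnc = float(cxc.mean()), float(cxnc.mean())
    pct = 100.0 * (m_cxc - m_cxnc) / m_cxnc if m_cxnc != 0 else np.nan
    return TraitContrast(trait, m_cxc, m_cxnc, pct, float(t), float(p),
                         len(cxc), len(cxnc))


def mummy_excess_test(tracked_litters,
                      population_mean: float = MUMMY_BASELINE):
    """One-sided one-sample t-test: are mummy counts in tracked CxC litters
    above the breed baseline?  Returns (sample_mean, p)."""
    counts = np.asarray(tracked_litters, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 litters")
    res = stats.ttest_1samp(counts, population_mean, alternative="greater")
    return float(counts.mean()), float(res.pvalue)


# ---------------------------------------------------------------------------
# Carrier frequency over time
# ---------------------------------------------------------------------------

def _half_year_bins(start: pd.Timestamp, end: pd.Timestamp) -> list[pd.Timestamp]:
    """Half-year bin edges aligned to Jan 1 / Jul 1, from the bin containing
    ``start`` through the one containing ``end``."""
    first = pd.Timestamp(start.year, 7 if start.month >= 7 else 1, 1)
    edges = [first]
    while edges[-1] <= end:
        prev = edges[-1]
        edges.append(pd.Timestamp(prev.year + (prev.month == 7),
                                  1 if prev.month == 7 else 7, 1))
    return edges


def cochran_armitage_trend(carriers, totals, scores=None) -> float:
    """Two-sided Cochran-Armitage test for a linear trend in proportions."""
    r = np.asarray(carriers, dtype=float)
    n = np.asarray(totals, dtype=float)
    x = np.arange(len(r), dtype=float) if scores is None else np.asarray(scores, float)
    N, R = n.sum(), r.sum()
    if N == 0 or R == 0 or R == N:
        return 1.0
    pbar = R / N
    t = (r * x).sum() - R * (n * x).sum() / N
    var = pbar * (1 - pbar) * ((n * x ** 2).sum() - (n * x).sum() ** 2 / N)
    if var <= 0:
        return 1.0
    z = t / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def frequency_over_time(carrier_statuses: dict[str, str],
                        pedigree: pd.DataFrame,
                        bin: str = "half_year",
                        start: str = "2006-07-01",
                        lifespan_years: float = 3.0):
    """Carrier frequency per half-year bin among the live population.

    An animal is counted as live in a bin if it was born on or before the bin
    end and within ``lifespan_years`` of the bin start (the data carry no
    death dates, so liveness is approximated by a fixed lifespan).

    Returns (series DataFrame with bin_start/n/carriers/freq, anova_p,
    trend_p).  ``anova_p`` is a one-way ANOVA across bins on animal-level
    carrier indicators; ``trend_p`` the Cochran-Armitage trend test.
    """
    if bin != "half_year":
        raise ValueError("only half_year binning is implemented")
    ped = pedigree.dropna(subset=["birth_date"])
    known = ped["animal"].map(carrier_statuses).isin(_CARRIER | _NONCARRIER)
    ped = ped[known]
    if ped.empty:
        raise ValueError("no dated animals with known status")
    is_carrier = ped["animal"].map(carrier_statuses).isin(_CARRIER).to_numpy()
    births = ped["birth_date"].to_numpy()

    start_ts = pd.Timestamp(start)
    edges = _half_year_bins(start_ts, ped["birth_date"].max())
    lifespan = pd.Timedelta(days=365.25 * lifespan_years)
    rows, groups = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        bin_end = hi - pd.Timedelta(days=1)
        alive = (births <= np.datetime64(bin_end)) \
            & (births > np.datetime64(lo - lifespan))
        n = int(alive.sum())
        if n == 0:
            rows.append({"bin_start": lo, "n": 0, "carriers": np.nan,
                         "freq": np.nan})
            continue
        c = int(is_carrier[alive].sum())
        rows.append({"bin_start": lo, "n": n, "carriers": c, "freq": c / n})
        groups.append(is_carrier[alive].astype(float))
    series = pd.DataFrame(rows)
    tested = series.dropna(subset=["freq"])
    if len(tested) >= 2 and len(groups) >= 2:
        anova_p = float(stats.f_oneway(*groups).pvalue)
        trend_p = cochran_armitage_trend(
            tested["carriers"].to_numpy(), tested["n"].to_numpy())
    else:
        anova_p = trend_p = np.nan
    return series, anova_p, trend_p
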