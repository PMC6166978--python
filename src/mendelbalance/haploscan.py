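"""Missing-homozygosity scanning for recessive lethal haplotypes.

A haplotype that is lethal in the homozygous state leaves a statistical
footprint in a genotyped population: among offspring of carrier x carrier
matings, homozygotes for the haplotype are absent (or strongly depleted)
relative to the Mendelian expectation computed from the parents' phased
genotypes.  This module builds haplotype windows, assigns per-animal carrier
status, computes trio-based expected homozygote counts (each offspring of
parents carrying s and d copies contributes p = (s/2)(d/2)), and tests the
observed count against the Poisson-binomial distribution of the sum of those
independent Bernoulli contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, PhasedPanel

DEPLETION_P_THRESHOLD = 5e-3  # significance threshold for a single tested haplotype


@dataclass(frozen=True)
class HaplotypeWindow:
    """A run of consecutive markers plus the target allele string over them.

    Marker indices are inclusive; ``allele_string`` holds allele codes
    (0 = A allele, 1 = B allele) for the tracked haplotype.
    """

    chrom: str
    start_marker_idx: int
    end_marker_idx: int
    allele_string: tuple[int, ...]

    def __post_init__(self):
        n = self.end_marker_idx - self.start_marker_idx + 1
        if n < 1:
            raise ValueError("empty window")
        if len(self.allele_string) != n:
            raise ValueError(
                f"allele string length {len(self.allele_string)} != window size {n}")

    @property
    def n_markers(self) -> int:
        return self.end_marker_idx - self.start_marker_idx + 1


@dataclass
class CarrierStatus:
    animal: str
    status: str          # wtwt | wtdel | deldel | unknown
    copies: int | None   # 0/1/2 or None when unknown

    _STATUS_BY_COPIES = {0: "wtwt", 1: "wtdel", 2: "deldel"}

    @classmethod
    def from_copies(cls, animal: str, copies: int | None) -> "CarrierStatus":
        if copies is None:
            return cls(animal, "unknown", None)
        return cls(animal, cls._STATUS_BY_COPIES[copies], copies)


@dataclass
class DepletionResult:
    window: HaplotypeWindow | None
    per_offspring_probs: np.ndarray
    expected: float
    observed: int
    p_value: float
    significant: bool
    n_excluded: int = 0


# ---------------------------------------------------------------------------
# Carrier status
# ---------------------------------------------------------------------------

def window_copies(panel: PhasedPanel, window: HaplotypeWindow) -> np.ndarray:
    """Copies of the target haplotype per animal; -1 where any window allele
    is missing on either haplotype."""
    lo, hi = window.start_marker_idx, window.end_marker_idx + 1
    if hi > len(panel.markers):
        raise ValueError("window extends past the marker map")
    chroms = panel.markers.table["chrom"].iloc[lo:hi].unique()
    if len(chroms) != 1 or chroms[0] != window.chrom:
        raise ValueError("window spans a chromosome boundary or wrong chrom")
    target = np.asarray(window.allele_string, dtype=np.int8)
    h1 = panel.hap1[:, lo:hi]
    h2 = panel.hap2[:, lo:hi]
    missing = ((h1 == MISSING) | (h2 == MISSING)).any(axis=1)
    copies = ((h1 == target).all(axis=1).astype(np.int8)
              + (h2 == target).all(axis=1).astype(np.int8))
    out = copies.astype(np.int8)
    out[missing] = -1
    return out


def window_carrier_status(panel: PhasedPanel,
                          window: HaplotypeWindow) -> list[CarrierStatus]:
    """Per-animal carrier status for the target haplotype (exact string match
    of either phased haplotype over the window)."""
    copies = window_copies(panel, window)
    return [CarrierStatus.from_copies(a, None if c < 0 else int(c))
            for a, c in zip(panel.animals, copies)]


# ---------------------------------------------------------------------------
# Expected homozygotes from trios
# ---------------------------------------------------------------------------

def expected_homozygotes(trios) -> tuple[np.ndarray, float, int]:
    """Per-offspring homozygote probabilities from parental carrier copies.

    ``trios`` is an iterable of (offspring_id, sire_copies, dam_copies); an
    offspring whose parents both have known copies contributes
    p = (sire_copies/2) * (dam_copies/2).  Offspring with an unknown parent
    are excluded (counted, not an error).

    Returns (per_offspring_probs, expected, n_excluded).
    """
    probs = []
    n_excluded = 0
    for _off, s, d in trios:
        if s is None or d is None or s < 0 or d < 0:
            n_excluded += 1
            continue
        if not (0 <= s <= 2 and 0 <= d <= 2):
            raise ValueError(f"parent copies must be 0/1/2, got {s}, {d}")
        probs.append((s / 2.0) * (d / 2.0))
    probs = np.asarray(probs, dtype=float)
    return probs, float(probs.sum()), n_excluded


# ---------------------------------------------------------------------------
# Poisson-binomial lower tail
# ---------------------------------------------------------------------------

def poisson_binomial_pmf(probs: np.ndarray) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_i) variables.

    Groups equal probabilities and convolves the resulting binomial blocks;
    equivalent to the one-at-a-time dynamic-programming convolution but much
    faster when the p_i take few distinct values (trio transmission
    probabilities are all in {1/4, 1/2, 1}).
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        return np.ones(1)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities outside [0, 1]")
    vals, counts = np.unique(probs, return_counts=True)
    pmf = np.ones(1)
    for p, k in zip(vals, counts):
        block = stats.binom.pmf(np.arange(k + 1), k, p)
        pmf = np.convolve(pmf, block)
    return pmf


def depletion_test(per_offspring_probs,
                   observed: int,
                   threshold: float = DEPLETION_P_THRESHOLD,
                   window: HaplotypeWindow | None = None,
                   n_excluded: int = 0) -> DepletionResult:
    """Exact lower-tail test of homozygote depletion.

    p = P(X <= observed) where X is the Poisson-binomial sum of the
    per-offspring homozygote probabilities; with equal p_i this is the exact
    binomial lower tail.
    """
    probs = np.asarray(per_offspring_probs, dtype=float)
    n = probs.size
    if observed < 0 or observed > n:
        raise ValueError(f"observed={observed} outside [0, {n}]")
    pmf = poisson_binomial_pmf(probs)
    p = float(min(1.0, pmf[: observed + 1].sum()))
    p = max(p, np.finfo(float).tiny)
    return DepletionResult(
        window=window,
        per_offspring_probs=probs,
        expected=float(probs.sum()),
        observed=int(observed),
        p_value=p,
        significant=p < threshold,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Mendelian ratio test and frequency summaries
# ---------------------------------------------------------------------------

def mendelian_ratio_test(genotype_counts, expected_ratio=(1, 2, 1)):
    """Pearson chi-square of genotype counts (wt/wt, wt/del, del/del) against
    a Mendelian ratio; returns (chi2, df, p)."""
    counts = np.asarray(genotype_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    total = counts.sum()
    if total <= 0:
        raise ValueError("no observations")
    ratio = np.asarray(expected_ratio, dtype=float)
    expected = total * ratio / ratio.sum()
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    df = len(counts) - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def carrier_freq_from_hap_freq(hap_freq: float) -> float:
    """Carrier frequency implied by a haplotype frequency measured in a
    population with no live homozygotes: every copy sits in a heterozygote,
    so carrier frequency = 2 x haplotype frequency."""
    if not 0 <= hap_freq <= 0.5:
        raise ValueError("haplotype frequency must be in [0, 0.5]")
    return 2.0 * hap_freq


def summarize_frequencies(statuses: list[CarrierStatus]):
    """(haplotype_freq, carrier_freq, expected_cxc_fraction) from known statuses.

    ``expected_cxc_fraction`` is carrier_freq**2, the random-mating expectation
    for the fraction of litters with two carrier parents.
    """
    copies = np.array([s.copies for s in statuses if s.copies is not None])
    if copies.size == 0:
        raise ValueError("no animals with known status")
    hap_freq = copies.sum() / (2.0 * copies.size)
    carrier_freq = float((copies >= 1).mean())
    return float(hap_freq), carrier_freq, carrier_freq ** 2


# ---------------------------------------------------------------------------
# Genome scan
# ---------------------------------------------------------------------------

def _pedigree_trio_index(panel: PhasedPanel, pedigree: pd.DataFrame):
    """Index arrays (offspring, sire, dam) for animals whose parents are both
    genotyped in the panel."""
    pos = {a: i for i, a in enumerate(panel.animals)}
    off, sire, dam = [], [], []
    for r in pedigree.itertuples(index=False):
        if r.animal in pos and r.sire in pos and r.dam in pos:
            off.append(pos[r.animal])
            sire.append(pos[r.sire])
            dam.append(pos[r.dam])
    return (np.asarray(off, dtype=np.intp),
            np.asarray(sire, dtype=np.intp),
            np.asarray(dam, dtype=np.intp))


def scan_genome(panel: PhasedPanel,
                pedigree: pd.DataFrame,
                window_markers: int = 25,
                threshold: float = DEPLETION_P_THRESHOLD,
                min_hap_freq: float = 0.01,
                bonferroni: bool = True) -> pd.DataFrame:
    """Slide a fixed-size window across every chromosome, track each distinct
    haplotype above ``min_hap_freq``, and run the trio-based depletion test
    for each.

    Windows truncated at chromosome ends are skipped.  When ``bonferroni`` is
    set, the significance call divides ``threshold`` by the number of tested
    (window, haplotype) pairs; raw p-values are always reported.

    Returns a DataFrame sorted by p-value with columns (chrom, start_idx,
    end_idx, start_marker, end_marker, haplotype, hap_freq, carrier_freq,
    expected, observed, p, significant).
    """
    off_idx, sire_idx, dam_idx = _pedigree_trio_index(panel, pedigree)
    mt = panel.markers.table
    rows = []
    for chrom in mt["chrom"].unique():
        cidx = np.flatnonzero((mt["chrom"] == chrom).to_numpy())
        for start in range(0, len(cidx) - window_markers + 1):
            lo = int(cidx[start])
            hi = lo + window_markers  # exclusive
            h1 = panel.hap1[:, lo:hi]
            h2 = panel.hap2[:, lo:hi]
            both = np.concatenate([h1, h2], axis=0)
            ok = ~(both == MISSING).any(axis=1)
            view = np.ascontiguousarray(both[ok]).view(
                np.dtype((np.void, window_markers))).ravel()
            uniq, counts = np.unique(view, return_counts=True)
            n_haps = ok.sum()
            candidates = uniq[counts / n_haps >= min_hap_freq]
            if candidates.size == 0:
                continue
            anim_missing = ((h1 == MISSING) | (h2 == MISSING)).any(axis=1)
            for hap_bytes in candidates:
                target = np.frombuffer(hap_bytes.tobytes(), dtype=np.int8)
                copies = ((h1 == target).all(axis=1).astype(np.int8)
                          + (h2 == target).all(axis=1).astype(np.int8))
                copies = np.where(anim_missing, -1, copies)
                known = copies >= 0
                hap_freq = copies[known].sum() / (2.0 * known.sum())
                carrier_freq = (copies[known] >= 1).mean()
                sc = copies[sire_idx]
                dc = copies[dam_idx]
                oc = copies[off_idx]
                usable = (sc >= 0) & (dc >= 0) & (oc >= 0)
                probs = (sc[usable] / 2.0) * (dc[usable] / 2.0)
                observed = int((oc[usable] == 2).sum())
                res = depletion_test(probs, observed, threshold=threshold)
                rows.append({
                    "chrom": chrom,
                    "start_idx": lo,
                    "end_idx": hi - 1,
                    "start_marker": mt["marker_id"].iat[lo],
                    "end_marker": mt["marker_id"].iat[hi - 1],
                    "haplotype": "".join(map(str, target)),
                    "hap_freq": hap_freq,
                    "carrier_freq": carrier_freq,
                    "expected": res.expected,
                    "observed": observed,
                    "p": res.p_value,
                    "n_excluded": int((~usable).sum()),
                })
    out = pd.DataFrame(rows)
    if out.empty:
        out["significant"] = pd.Series(dtype=bool)
        return out
    alpha = threshold / len(out) if bonferroni else threshold
    out["significant"] = out["p"] < alpha
    return out.sort_values("p", kind="stable").reset_index(drop=True)
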