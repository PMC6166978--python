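"""Synthetic breeding-population generator with known ground truth.

Emulates the statistical structure of a purebred pig line segregating one
recessive lethal haplotype with heterozygote advantage, at a scale where the
whole detection pipeline runs in seconds:

* a phased SNP panel whose haplotypes descend from a small founder pool
  (giving realistic haplotype sharing), with the lethal embedded as a
  distinct allele string over a run of consecutive markers;
* discrete generations with AI-style sire reuse, recombination during
  transmission, and Poisson litter sizes;
* homozygous conceptuses die in gestation: most become mummified piglets,
  a few are stillborn or weak liveborns that die before entering the
  genotyped panel (the panel emulates live selection candidates);
* Log R Ratio intensities depressed at four markers inside the deletion;
* EBV tables built by running the parent-average/individual mixed-model
  equations forward from true breeding values, so that deregression inverts
  them exactly;
* truth labels for every animal and litter.

Same seed, same bundle, byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ase_impact import ASECount, GeneModel
from .core_io import MISSING, MarkerMap, PhasedPanel
from .haploscan import HaplotypeWindow


@dataclass
class TraitSpec:
    h2: float
    mean: float
    sd: float                      # genetic standard deviation
    carrier_shift: float           # additive shift for carriers, trait units


def _default_traits() -> dict[str, TraitSpec]:
    # shifts: +2.7% of the index mean for TSI, +12.4% for growth, and a
    # lower litter birth weight for carriers
    return {
        "TSI": TraitSpec(h2=0.40, mean=100.0, sd=10.0, carrier_shift=2.7),
        "GROWTH": TraitSpec(h2=0.30, mean=100.0, sd=10.0, carrier_shift=12.4),
        "LBW": TraitSpec(h2=0.25, mean=1400.0, sd=120.0, carrier_shift=-16.7),
    }


@dataclass
class SimConfig:
    n_founders: int = 550
    n_generations: int = 3
    litters_per_dam: int = 1
    n_dams: int = 450
    n_sires: int = 55
    q0: float = 0.054                  # lethal haplotype frequency
    panel_markers: int = 120
    n_chromosomes: int = 2
    window_markers: int = 25
    founder_pool: int = 30             # distinct founder haplotypes per genome
    recomb_rate: float = 0.0004        # crossover prob per 40kb marker interval
    tnb_mean: float = 16.0             # conceptions per litter
    mummy_baseline: float = 0.35       # background mummies per litter
    stillborn_baseline: float = 0.4    # background stillborns per litter
    hom_fate: tuple[float, float, float] = (0.8, 0.15, 0.05)  # mummy/stillborn/weak
    lrr_params: dict = field(default_factory=lambda: {
        "wtwt": (0.0, 0.25), "wtdel": (-0.6, 0.30), "deldel": (-2.5, 0.8)})
    tsi_mean: float = 100.0
    tsi_sd: float = 10.0
    carrier_tsi_shift_pct: float = 2.7
    carrier_growth_shift_pct: float = 12.4
    carrier_birthweight_shift: float = -16.7   # grams, <= 0
    traits: dict[str, TraitSpec] = field(default_factory=_default_traits)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.q0 < 0.5:
            raise ValueError("q0 must be in [0, 0.5)")
        if abs(sum(self.hom_fate) - 1.0) > 1e-9:
            raise ValueError("hom_fate probabilities must sum to 1")
        if self.carrier_birthweight_shift > 0:
            raise ValueError("carrier_birthweight_shift must be <= 0")
        if self.window_markers > self.panel_markers // self.n_chromosomes:
            raise ValueError("lethal window longer than a chromosome")
        # keep the configured shifts and the trait table in sync; the trait
        # sd is the genetic sd, sqrt(h2) x the index sd
        tsi = self.traits["TSI"]
        tsi.mean = self.tsi_mean
        tsi.sd = math.sqrt(tsi.h2) * self.tsi_sd
        tsi.carrier_shift = self.carrier_tsi_shift_pct / 100.0 * tsi.mean
        growth = self.traits["GROWTH"]
        growth.carrier_shift = (
            self.carrier_growth_shift_pct / 100.0 * growth.mean)
        self.traits["LBW"].carrier_shift = self.carrier_birthweight_shift


@dataclass
class TruthLabels:
    copies: pd.Series              # true lethal copies per panel animal
    litters: pd.DataFrame          # per-litter conceived/homozygote accounting
    window: HaplotypeWindow        # true lethal window in the emitted panel
    deletion_markers: list[str]    # the 4 low-LRR markers
    debv_true: pd.DataFrame | None = None  # animal, trait, y_i (own-record value)


@dataclass
class Bundle:
    panel: PhasedPanel
    pedigree: pd.DataFrame
    litters: pd.DataFrame
    lrr: pd.DataFrame
    ebv: pd.DataFrame
    truth: TruthLabels
    config: SimConfig

    def carrier_statuses(self) -> dict[str, str]:
        return {a: ("wtdel" if c >= 1 else "wtwt")
                for a, c in self.truth.copies.items()}


# ---------------------------------------------------------------------------
# Haplotype machinery
# ---------------------------------------------------------------------------

def _founder_pool(rng, cfg) -> tuple[np.ndarray, np.ndarray]:
    """(pool haplotypes (K, M) int8, chromosome id per marker)."""
    m_per = cfg.panel_markers // cfg.n_chromosomes
    M = m_per * cfg.n_chromosomes
    chrom_of = np.repeat(np.arange(cfg.n_chromosomes), m_per)
    freq = rng.uniform(0.15, 0.85, size=M)
    pool = (rng.random((cfg.founder_pool, M)) < freq).astype(np.int8)
    return pool, chrom_of


def _gametes(rng, h1, h2, n, chrom_of, rate) -> np.ndarray:
    """Draw n gametes from one parent with recombination; chromosomes
    assort independently."""
    M = h1.shape[0]
    switch = rng.random((n, M)) < rate
    starts = np.r_[True, chrom_of[1:] != chrom_of[:-1]]
    switch[:, starts] = rng.random((n, starts.sum())) < 0.5
    sel = np.bitwise_xor.accumulate(switch, axis=1)
    return np.where(sel, h2[None, :], h1[None, :]).astype(np.int8)


# ---------------------------------------------------------------------------
# EBV machinery: forward parent-average/individual mixed-model equations
# ---------------------------------------------------------------------------

def _zpz_from_reliabilities(rel, rel_pa, lam):
    """Effective information contents (Z'Z_pa, Z'Z_i) implied by published
    reliabilities; same 2x2 system that deregression inverts."""
    A = (0.5 - rel_pa) / lam
    B = (1.0 - rel) / lam
    u = (1.0 + np.sqrt(1.0 + 16.0 * A * B * lam * lam)) / (2.0 * A)
    v = 4.0 * A * lam * lam / (A * u - 1.0)
    return np.maximum(u - 4.0 * lam, 1e-6), np.maximum(v - 2.0 * lam, 1e-6)


def _forward_ebv(rng, g, pa_true, rel, rel_pa, lam, sigma_g):
    """Simulate a genetic evaluation: pseudo-records for the parent average
    and the individual, solved through the 2x2 mixed-model equations.

    Returns (ebv_dev, ebv_pa_dev, y_i) as deviations from the trait mean;
    y_i is the individual's own-record value that deregression recovers.
    """
    zpz_pa, zpz_i = _zpz_from_reliabilities(rel, rel_pa, lam)
    y_pa = pa_true + rng.normal(0, sigma_g * np.sqrt(lam / zpz_pa))
    y_i = g + rng.normal(0, sigma_g * np.sqrt(lam / zpz_i))
    # C = [[zpz_pa + 4L, -2L], [-2L, zpz_i + 2L]];  C ghat = [zpz_pa y_pa, zpz_i y_i]
    a, b, d = zpz_pa + 4 * lam, -2 * lam, zpz_i + 2 * lam
    det = a * d - b * b
    r1, r2 = zpz_pa * y_pa, zpz_i * y_i
    ghat_pa = (d * r1 - b * r2) / det
    ghat_i = (-b * r1 + a * r2) / det
    return ghat_i, ghat_pa, y_i


# ---------------------------------------------------------------------------
# Population generator
# ---------------------------------------------------------------------------

def generate_population(cfg: SimConfig | None = None) -> Bundle:
    """Simulate the full bundle; see the module docstring for the model."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    pool, chrom_of = _founder_pool(rng, cfg)
    M = pool.shape[1]
    m_per = M // cfg.n_chromosomes

    # lethal window: consecutive markers on the last chromosome
    win_chrom = cfg.n_chromosomes - 1
    win_lo = win_chrom * m_per + (m_per - cfg.window_markers) // 2
    win_hi = win_lo + cfg.window_markers - 1
    target = pool[0, win_lo:win_hi + 1].copy()
    # make the lethal string unique within the founder pool
    for k in range(1, cfg.founder_pool):
        if np.array_equal(pool[k, win_lo:win_hi + 1], target):
            pool[k, win_lo] ^= 1

    def hap_copies(h):  # lethal copies carried by a haplotype array (n, M)
        return (h[:, win_lo:win_hi + 1] == target).all(axis=1)

    # founders: background haplotypes from the pool; the carrier count is set
    # exactly to the live-population equilibrium 2q(1-q)/(1-q^2) (carriers are
    # all heterozygous, as in a live population with no del/del animals)
    n0 = cfg.n_founders
    h1 = pool[rng.integers(1, cfg.founder_pool, size=n0)].copy()
    h2 = pool[rng.integers(1, cfg.founder_pool, size=n0)].copy()
    c_eq = 2 * cfg.q0 * (1 - cfg.q0) / (1 - cfg.q0 ** 2)
    carriers0 = rng.choice(n0, size=int(round(c_eq * n0)), replace=False)
    h1[carriers0] = pool[0]

    ids = [f"A{n:06d}" for n in range(n0)]
    hap1_rows, hap2_rows = [h1], [h2]
    sex = list(rng.choice(["male", "female"], size=n0, p=[0.5, 0.5]))
    sires: list[str | float] = [np.nan] * n0
    dams: list[str | float] = [np.nan] * n0
    base_date = np.datetime64("2006-01-01")
    birth = list(base_date + rng.integers(0, 180, size=n0).astype("timedelta64[D]"))
    generation = [0] * n0
    idx_of = {a: i for i, a in enumerate(ids)}

    litter_rows, truth_litter_rows = [], []
    gen_members = [list(range(n0))]
    counter = n0
    H1 = np.concatenate(hap1_rows)
    H2 = np.concatenate(hap2_rows)

    for g in range(1, cfg.n_generations + 1):
        prev = gen_members[-1]
        females = [i for i in prev if sex[i] == "female"]
        males = [i for i in prev if sex[i] == "male"]
        if len(females) < 2 or len(males) < 1:
            raise ValueError("breeding population collapsed; enlarge config")

        # parent sampling stratified by carrier status: the balanced
        # stationary state keeps carriers at 2*q0 among breeding animals
        # (heterozygote advantage offsets homozygote loss), which the
        # generator imposes directly rather than simulating selection
        def pick_parents(cands: list[int], n_pick: int) -> np.ndarray:
            cands = np.asarray(cands)
            is_c = (hap_copies(H1[cands]) | hap_copies(H2[cands]))
            car, non = cands[is_c], cands[~is_c]
            n_pick = min(n_pick, len(cands))
            n_car = min(len(car), int(round(2 * cfg.q0 * n_pick)))
            chosen = np.concatenate([
                rng.choice(car, size=n_car, replace=False),
                rng.choice(non, size=min(n_pick - n_car, len(non)),
                           replace=False)])
            return chosen

        dam_idx = pick_parents(females, cfg.n_dams)
        sire_pool = pick_parents(males, cfg.n_sires)
        # AI-style sire reuse: cycle a shuffled sire list over the litters so
        # every sire serves an (almost) equal number of matings
        n_litters_gen = len(dam_idx) * cfg.litters_per_dam
        sire_seq = np.resize(rng.permutation(sire_pool), n_litters_gen)
        litter_no = 0
        new_members = []
        new_h1, new_h2 = [], []
        for dam_i in dam_idx:
            for parity in range(1, cfg.litters_per_dam + 1):
                sire_i = int(sire_seq[litter_no])
                litter_no += 1
                conceived = int(rng.poisson(cfg.tnb_mean))
                litter_id = f"L{len(litter_rows):05d}"
                date = (birth[dam_i]
                        + np.timedelta64(int(360 + parity * 170
                                             + rng.integers(0, 60)), "D"))
                if conceived == 0:
                    continue
                gs = _gametes(rng, H1[sire_i], H2[sire_i], conceived,
                              chrom_of, cfg.recomb_rate)
                gd = _gametes(rng, H1[dam_i], H2[dam_i], conceived,
                              chrom_of, cfg.recomb_rate)
                copies = hap_copies(gs).astype(int) + hap_copies(gd).astype(int)
                is_dd = copies == 2
                n_dd = int(is_dd.sum())
                fates = rng.choice(3, size=n_dd, p=cfg.hom_fate)  # 0 mum,1 sb,2 weak
                dd_mum = int((fates == 0).sum())
                dd_sb = int((fates == 1).sum())
                dd_weak = n_dd - dd_mum - dd_sb
                bg_mum = int(rng.poisson(cfg.mummy_baseline))
                non_dd = np.flatnonzero(~is_dd)
                bg_sb = min(int(rng.poisson(cfg.stillborn_baseline)), len(non_dd))
                sb_pick = rng.choice(non_dd, size=bg_sb, replace=False) \
                    if bg_sb else np.array([], dtype=int)

                tnb = conceived - dd_mum
                stillborn = dd_sb + bg_sb
                nba = tnb - stillborn
                mummified = bg_mum + dd_mum
                litter_rows.append({
                    "litter_id": litter_id, "sire": ids[sire_i],
                    "dam": ids[dam_i], "farm": f"F{rng.integers(1, 3)}",
                    "parity": parity, "tnb": tnb, "nba": nba,
                    "stillborn": stillborn, "mummified": mummified,
                    "date": pd.Timestamp(date),
                })
                truth_litter_rows.append({
                    "litter_id": litter_id, "conceived": conceived,
                    "n_deldel": n_dd, "deldel_mummy": dd_mum,
                    "deldel_stillborn": dd_sb, "deldel_weak": dd_weak,
                    "bg_mummy": bg_mum, "bg_stillborn": bg_sb,
                    "cxc": bool(hap_copies(H1[[sire_i]])[0]
                                | hap_copies(H2[[sire_i]])[0])
                    and bool(hap_copies(H1[[dam_i]])[0]
                             | hap_copies(H2[[dam_i]])[0]),
                })
                # panel entrants: liveborn, excluding weak del/del (die < 24h)
                keep = np.flatnonzero(~is_dd)
                keep = keep[~np.isin(keep, sb_pick)]
                for j in keep:
                    ids.append(f"A{counter:06d}")
                    idx_of[ids[-1]] = len(ids) - 1
                    counter += 1
                    sires.append(ids[sire_i])
                    dams.append(ids[dam_i])
                    sex.append("male" if rng.random() < 0.5 else "female")
                    birth.append(date)
                    generation.append(g)
                    new_members.append(len(ids) - 1)
                    new_h1.append(gs[j])
                    new_h2.append(gd[j])
        if new_h1:
            H1 = np.concatenate([H1, np.asarray(new_h1, dtype=np.int8)])
            H2 = np.concatenate([H2, np.asarray(new_h2, dtype=np.int8)])
        gen_members.append(new_members)

    # ------------------------------------------------------------------ panel
    m_ids = [f"SNP{c + 17}_{(i % m_per) + 1:03d}"
             for i, c in enumerate(chrom_of)]
    marker_table = pd.DataFrame({
        "marker_id": m_ids,
        "chrom": [str(c + 17) for c in chrom_of],
        "pos_bp": np.concatenate([
            np.arange(1, m_per + 1) * 40_000 + 1_000_000
            for _ in range(cfg.n_chromosomes)]),
        "allele_a": "A",
        "allele_b": "B",
    })
    panel = PhasedPanel(MarkerMap(marker_table), list(ids), H1.copy(), H2.copy())

    pedigree = pd.DataFrame({
        "animal": ids, "sire": sires, "dam": dams, "sex": sex,
        "birth_date": pd.to_datetime(birth), "generation": generation,
    })
    litters = pd.DataFrame(litter_rows)
    truth_litters = pd.DataFrame(truth_litter_rows)

    copies_all = (hap_copies(H1).astype(int) + hap_copies(H2).astype(int))
    copies = pd.Series(copies_all, index=ids, name="copies")

    # ------------------------------------------------------------------ LRR
    del_marker_idx = np.arange(win_lo + 10, win_lo + 14)
    lrr_cols = np.arange(win_lo, win_hi + 1)
    n = len(ids)
    lrr = rng.normal(0.0, cfg.lrr_params["wtwt"][1], size=(n, len(lrr_cols)))
    for cls, copy_n in (("wtdel", 1), ("deldel", 2)):
        mu, sd = cfg.lrr_params[cls]
        mask = copies_all == copy_n
        for k, col in enumerate(lrr_cols):
            if col in del_marker_idx:
                lrr[mask, k] = rng.normal(mu, sd, size=mask.sum())
    lrr_df = pd.DataFrame(lrr, index=pd.Index(ids, name="animal"),
                          columns=[m_ids[c] for c in lrr_cols])

    # ------------------------------------------------------------------ EBV
    carrier = (copies_all >= 1).astype(float)
    ebv_rows, debv_true_rows = [], []
    for trait, ts in cfg.traits.items():
        sigma_g = ts.sd
        lam = (1 - ts.h2) / ts.h2
        u = np.empty(n)
        u[:n0] = rng.normal(0, sigma_g, size=n0)
        for i in range(n0, n):
            si, di = idx_of[sires[i]], idx_of[dams[i]]
            u[i] = 0.5 * (u[si] + u[di]) + rng.normal(0, sigma_g / math.sqrt(2))
        g_true = u + ts.carrier_shift * carrier
        rel = rng.uniform(0.5, 0.9, size=n)
        rel_pa = rng.uniform(0.15, 0.35, size=n)
        pa_true = np.zeros(n)
        for i in range(n0, n):
            pa_true[i] = 0.5 * (g_true[idx_of[sires[i]]]
                                + g_true[idx_of[dams[i]]])
        ghat_i, ghat_pa, y_i = _forward_ebv(rng, g_true, pa_true, rel, rel_pa,
                                            lam, sigma_g)
        for i in range(n):
            ebv_rows.append({
                "animal": ids[i], "trait": trait,
                "ebv": ts.mean + ghat_i[i], "ebv_pa": ts.mean + ghat_pa[i],
                "rel": rel[i], "rel_pa": rel_pa[i], "h2": ts.h2,
            })
            debv_true_rows.append({"animal": ids[i], "trait": trait,
                                   "y_i": ts.mean + y_i[i],
                                   "g_true": ts.mean + g_true[i]})
    ebv = pd.DataFrame(ebv_rows)
    debv_true = pd.DataFrame(debv_true_rows)

    window = HaplotypeWindow(chrom=str(win_chrom + 17),
                             start_marker_idx=win_lo,
                             end_marker_idx=win_hi,
                             allele_string=tuple(int(x) for x in target))
    truth = TruthLabels(copies=copies, litters=truth_litters, window=window,
                        deletion_markers=[m_ids[c] for c in del_marker_idx],
                        debv_true=debv_true)
    return Bundle(panel, pedigree, litters, lrr_df, ebv, truth, cfg)


# ---------------------------------------------------------------------------
# Expression / transcript fixture generator
# ---------------------------------------------------------------------------

_NONSTOP_CODONS = [a + b + c
                   for a in "ACGT" for b in "ACGT" for c in "ACGT"
                   if a + b + c not in ("TAA", "TAG", "TGA")]


def build_fixture_gene(seed: int = 0) -> tuple[GeneModel, tuple[int, int]]:
    """Engineer a 28-exon gene whose deletion-induced skip of exons 20-27
    (4 coding + 4 3'UTR exons) frameshifts the transcript: translation reads
    11 novel residues into the former 3'UTR before a premature stop, turning
    the 865-residue wild-type protein into a 694-residue mutant.

    Returns (GeneModel, deletion interval).  This is a synthetic stand-in
    built to the published impact arithmetic, not real gene coordinates.
    """
    rng = np.random.default_rng(seed)
    n_codons = 865
    codons = [_NONSTOP_CODONS[k]
              for k in rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)]
    codons[0] = "ATG"
    codons[683] = "GAA"   # residue 684 = E; mutant reads G+TG = V here
    cds = "".join(codons) + "TAA"                    # 2598 nt
    utr5 = "".join(rng.choice(list("ACGT"), size=30))

    # coding nt per exon: exons 1-19 carry 683 codons + 1 nt (frameshifting
    # remainder), exons 20-23 carry the rest including the stop
    coding_1_19 = [130] + [106] * 17 + [118]         # sums to 2050
    coding_20_23 = [137, 137, 137, 137]              # sums to 548
    utr3_23 = "".join(rng.choice(list("ACGT"), size=50))
    utr3_24_27 = ["".join(rng.choice(list("ACGT"), size=80)) for _ in range(4)]
    # exon 28: frameshifted read-through = "TG" completing a codon with the
    # dangling G of exon 19, then 10 Ala codons, then a stop
    exon28 = "TG" + "GCT" * 10 + "TAA" + "".join(rng.choice(list("ACGT"), size=100))

    seqs = []
    pos = 0
    for k, ncod in enumerate(coding_1_19):
        s = cds[pos:pos + ncod]
        pos += ncod
        seqs.append((utr5 + s) if k == 0 else s)
    for ncod in coding_20_23:
        seqs.append(cds[pos:pos + ncod])
        pos += ncod
    seqs[-1] += utr3_23
    seqs.extend(utr3_24_27)
    seqs.append(exon28)

    exons, start = [], 1_000
    for s in seqs:
        exons.append((start, start + len(s) - 1))
        start += len(s) + 100   # 100-nt introns
    cds_start = exons[0][0] + len(utr5)
    cds_end = exons[22][0] + coding_20_23[-1] - 1    # last nt of the stop codon
    model = GeneModel(gene="FIXTURE9", strand="+", exons=exons,
                      cds_start=cds_start, cds_end=cds_end, exon_seqs=seqs)
    # deletion spans exons 20..27 (indices 19..26); exons 19 and 28 survive
    return model, (exons[19][0] - 50, exons[26][1] + 50)


def generate_expression_data(cfg: SimConfig | None = None,
                             n_het_sites: int = 50,
                             imbalance_ratio: float = 3.0,
                             n_control_sites: int = 50,
                             depth_mean: float = 100.0,
                             depth_dispersion: float = 5.0,
                             seed: int | None = None):
    """ASE read-count table plus the engineered gene fixture.

    Carrier sites draw wild-type counts ~ Binomial(depth, ratio/(1+ratio));
    control sites are balanced (p = 0.5).  Depth ~ NegBinomial with the given
    mean and dispersion (gamma-Poisson), minimum 1.

    Returns (counts, truth DataFrame, GeneModel, deletion interval).
    """
    if imbalance_ratio <= 0:
        raise ValueError("imbalance_ratio must be > 0")
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    p_imb = imbalance_ratio / (1.0 + imbalance_ratio)
    counts, truth_rows = [], []
    for i in range(n_het_sites + n_control_sites):
        imbalanced = i < n_het_sites
        lam = rng.gamma(depth_dispersion, depth_mean / depth_dispersion)
        depth = max(1, int(rng.poisson(lam)))
        p = p_imb if imbalanced else 0.5
        wt = int(rng.binomial(depth, p))
        counts.append(ASECount(locus=f"18:{39_500_000 + i * 997}",
                               gene="FIXTURE9" if imbalanced else f"CTRL{i}",
                               del_allele="C", alt_allele="T",
                               del_count=depth - wt, wt_count=wt))
        truth_rows.append({"locus": counts[-1].locus, "imbalanced": imbalanced,
                           "true_wt_fraction": p})
    model, deletion = build_fixture_gene(seed=cfg.seed if seed is None else seed)
    return counts, pd.DataFrame(truth_rows), model, deletion
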