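"""Readers, writers and QC filters for breeding-population data.

Handles the standard inputs of a lethal-haplotype analysis: phased SNP
genotypes (VCF or a simple haplotype TSV), pedigree, litter records,
per-marker Log R Ratio intensities and EBV tables.  Coordinates are 1-based
inclusive throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1  # haplotype allele code for missing
A_ALLELE = 0
B_ALLELE = 1

PEDIGREE_COLUMNS = ["animal", "sire", "dam", "sex", "birth_date"]
LITTER_COLUMNS = [
    "litter_id", "sire", "dam", "farm", "parity",
    "tnb", "nba", "stillborn", "mummified", "date",
]
EBV_COLUMNS = ["animal", "trait", "ebv", "rel", "rel_pa", "h2"]


class ValidationError(ValueError):
    """Raised when an input file violates a documented invariant."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class MarkerMap:
    """Marker coordinates and allele codes.

    ``table`` has columns (marker_id, chrom, pos_bp, allele_a, allele_b);
    positions are 1-based and strictly increasing within a chromosome.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        if t["marker_id"].duplicated().any():
            dup = t.loc[t["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValidationError(f"duplicate marker id: {dup}")
        for chrom, grp in t.groupby("chrom", sort=False):
            pos = grp["pos_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(
                    f"marker positions not strictly increasing on {chrom}")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    def index_of(self, marker_id: str) -> int:
        hits = np.flatnonzero(self.marker_ids == marker_id)
        if len(hits) == 0:
            raise KeyError(f"marker {marker_id} not in map")
        return int(hits[0])


@dataclass
class PhasedPanel:
    """Phased genotypes: two haplotype allele vectors per animal.

    ``hap1``/``hap2`` are int8 arrays of shape (n_animals, n_markers) with
    values in {0 (A allele), 1 (B allele), -1 (missing)}.
    """

    markers: MarkerMap
    animals: list[str]
    hap1: np.ndarray
    hap2: np.ndarray

    def __post_init__(self) -> None:
        n, m = len(self.animals), len(self.markers)
        for h in (self.hap1, self.hap2):
            if h.shape != (n, m):
                raise ValidationError(
                    f"haplotype matrix shape {h.shape} != ({n}, {m})")

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    def genotypes(self) -> np.ndarray:
        """B-allele dosage per animal x marker; -1 where either allele missing."""
        g = self.hap1 + self.hap2
        g[(self.hap1 == MISSING) | (self.hap2 == MISSING)] = MISSING
        return g

    def subset(self, animal_idx=None, marker_idx=None) -> "PhasedPanel":
        a = np.arange(self.n_animals) if animal_idx is None else np.asarray(animal_idx)
        m = np.arange(len(self.markers)) if marker_idx is None else np.asarray(marker_idx)
        return PhasedPanel(
            markers=MarkerMap(self.markers.table.iloc[m].reset_index(drop=True)),
            animals=[self.animals[i] for i in a],
            hap1=self.hap1[np.ix_(a, m)].copy(),
            hap2=self.hap2[np.ix_(a, m)].copy(),
        )


# ---------------------------------------------------------------------------
# Phased genotype IO
# ---------------------------------------------------------------------------

def _infer_format(path: str | Path) -> str:
    s = str(path)
    return "vcf" if s.endswith((".vcf", ".vcf.gz")) else "tsv"


def load_phased_genotypes(path: str | Path, format: str | None = None) -> PhasedPanel:
    """Load a phased panel from a VCF (phased GT) or haplotype TSV.

    The TSV dialect is one row per animal per haplotype:
    ``animal_id  hap_index(1|2)  allele  allele ...`` following a header row
    ``animal  hap  <marker ids...>`` plus a ``#marker`` preamble giving the map
    (marker_id, chrom, pos, allele_a, allele_b).  Missing alleles are ``.``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "vcf":
        return _load_vcf(path)
    if fmt == "tsv":
        return _load_hap_tsv(path)
    raise ValueError(f"unknown format {fmt!r}")


def _load_vcf(path: Path) -> PhasedPanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    animals = list(vcf.samples)
    rows, h1, h2 = [], [], []
    for var in vcf:
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS,
                     var.REF, var.ALT[0] if var.ALT else "."))
        g = np.asarray(var.genotypes)  # columns: allele1, allele2, phased
        unphased = np.flatnonzero((g[:, 2] == 0) & (g[:, 0] >= 0) & (g[:, 1] >= 0))
        if len(unphased):
            raise ValidationError(
                f"unphased genotype at {var.CHROM}:{var.POS} "
                f"for sample {animals[unphased[0]]}")
        a1 = g[:, 0].astype(np.int8)
        a2 = g[:, 1].astype(np.int8)
        a1[a1 < 0] = MISSING
        a2[a2 < 0] = MISSING
        h1.append(a1)
        h2.append(a2)
    markers = MarkerMap(pd.DataFrame(
        rows, columns=["marker_id", "chrom", "pos_bp", "allele_a", "allele_b"]))
    panel = PhasedPanel(markers, animals,
                        np.array(h1, dtype=np.int8).T.copy(),
                        np.array(h2, dtype=np.int8).T.copy())
    return _sort_markers(panel)


def _load_hap_tsv(path: Path) -> PhasedPanel:
    marker_rows = []
    data_lines = []
    header = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#marker"):
                _, mid, chrom, pos, a, b = line.split("\t")
                marker_rows.append((mid, chrom, int(pos), a, b))
            elif header is None:
                header = line.split("\t")
            else:
                data_lines.append(line.split("\t"))
    if not marker_rows:
        raise ValidationError(f"{path}: no #marker preamble")
    markers = MarkerMap(pd.DataFrame(
        marker_rows, columns=["marker_id", "chrom", "pos_bp", "allele_a", "allele_b"]))
    allele_a = markers.table["allele_a"].to_numpy()
    allele_b = markers.table["allele_b"].to_numpy()

    per_animal: dict[str, dict[int, np.ndarray]] = {}
    for parts in data_lines:
        animal, hap_idx, alleles = parts[0], int(parts[1]), parts[2:]
        if len(alleles) != len(markers):
            raise ValidationError(
                f"animal {animal} hap {hap_idx}: {len(alleles)} alleles "
                f"for {len(markers)} markers")
        codes = np.full(len(markers), MISSING, dtype=np.int8)
        arr = np.asarray(alleles)
        codes[arr == allele_a] = A_ALLELE
        codes[arr == allele_b] = B_ALLELE
        bad = ~np.isin(arr, ["."]) & (codes == MISSING)
        if bad.any():
            j = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"animal {animal}: allele {arr[j]!r} not in "
                f"{{{allele_a[j]},{allele_b[j]}}} at marker "
                f"{markers.marker_ids[j]}")
        per_animal.setdefault(animal, {})[hap_idx] = codes
    animals = list(per_animal)
    n, m = len(animals), len(markers)
    h1 = np.full((n, m), MISSING, dtype=np.int8)
    h2 = np.full((n, m), MISSING, dtype=np.int8)
    for i, a in enumerate(animals):
        haps = per_animal[a]
        if set(haps) != {1, 2}:
            raise ValidationError(f"animal {a}: expected haplotype rows 1 and 2")
        h1[i] = haps[1]
        h2[i] = haps[2]
    return _sort_markers(PhasedPanel(markers, animals, h1, h2))


def _sort_markers(panel: PhasedPanel) -> PhasedPanel:
    order = panel.markers.table.sort_values(
        ["chrom", "pos_bp"], kind="stable").index.to_numpy()
    if np.array_equal(order, np.arange(len(panel.markers))):
        return panel
    return panel.subset(marker_idx=order)


def write_phased_tsv(panel: PhasedPanel, path: str | Path) -> None:
    """Write a panel in the haplotype TSV dialect of :func:`load_phased_genotypes`."""
    t = panel.markers.table
    allele = {A_ALLELE: t["allele_a"].to_numpy(), B_ALLELE: t["allele_b"].to_numpy()}
    with open(path, "w") as fh:
        for row in t.itertuples(index=False):
            fh.write(f"#marker\t{row.marker_id}\t{row.chrom}\t{row.pos_bp}"
                     f"\t{row.allele_a}\t{row.allele_b}\n")
        fh.write("animal\thap\t" + "\t".join(t["marker_id"]) + "\n")
        cols = np.arange(len(t))
        for i, animal in enumerate(panel.animals):
            for hap_idx, h in ((1, panel.hap1), (2, panel.hap2)):
                codes = h[i]
                out = np.where(codes == MISSING, ".",
                               np.where(codes == A_ALLELE, allele[A_ALLELE][cols],
                                        allele[B_ALLELE][cols]))
                fh.write(f"{animal}\t{hap_idx}\t" + "\t".join(out) + "\n")


def write_phased_vcf(panel: PhasedPanel, path: str | Path) -> None:
    """Write the panel as a minimal phased VCF (allele A as REF, B as ALT)."""
    t = panel.markers.table
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in t["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.animals) + "\n")
        for j, row in enumerate(t.itertuples(index=False)):
            def gt(code: int) -> str:
                return "." if code == MISSING else str(int(code))
            calls = "\t".join(
                f"{gt(panel.hap1[i, j])}|{gt(panel.hap2[i, j])}"
                for i in range(panel.n_animals))
            fh.write(f"{row.chrom}\t{row.pos_bp}\t{row.marker_id}\t{row.allele_a}"
                     f"\t{row.allele_b}\t.\t.\t.\tGT\t{calls}\n")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact test for Hardy-Weinberg proportions on genotype counts.

    Conditional on the observed allele counts, enumerates every possible
    heterozygote count and sums the probabilities of all configurations no
    more probable than the observed one (plain exact test, no mid-p).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("negative genotype count")
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    na = 2 * n_aa + n_ab  # count of the A allele
    n_rare = min(na, 2 * n - na)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(n_ab = h | allele counts) via lgamma, normalized below
    logs = np.array([
        -math.lgamma((n_rare - h) / 2 + 1)
        - math.lgamma(n - (n_rare + h) / 2 + 1)
        - math.lgamma(h + 1) + h * math.log(2)
        for h in hets
    ])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[np.flatnonzero(hets == n_ab)[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    removed_animals: pd.DataFrame   # columns: animal, reason, value
    removed_markers: pd.DataFrame   # columns: marker_id, reason, value

    def summary(self) -> str:
        return (f"{len(self.removed_animals)} animals and "
                f"{len(self.removed_markers)} markers removed")


def qc_filter(panel: PhasedPanel,
              animal_missing_max: float = 0.20,
              marker_callrate_min: float = 0.85,
              maf_min: float = 0.01,
              hwe_p_min: float = 1e-6) -> tuple[PhasedPanel, QCReport]:
    """Standard SNP-chip QC: drop high-missingness animals first, then markers
    failing call rate, minor allele frequency or the HWE exact test.

    Marker statistics are recomputed on the retained animal set.  Animals are
    removed when their missing-genotype fraction exceeds ``animal_missing_max``;
    markers are removed when call rate < ``marker_callrate_min``, MAF <=
    ``maf_min``, or HWE exact p < ``hwe_p_min``.
    """
    for name, v in [("animal_missing_max", animal_missing_max),
                    ("marker_callrate_min", marker_callrate_min),
                    ("maf_min", maf_min), ("hwe_p_min", hwe_p_min)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    if panel.n_animals == 0 or len(panel.markers) == 0:
        raise ValueError("empty panel")

    g = panel.genotypes()
    miss_frac = (g == MISSING).mean(axis=1)
    keep_a = miss_frac <= animal_missing_max
    removed_animals = pd.DataFrame({
        "animal": np.asarray(panel.animals)[~keep_a],
        "reason": "missingness",
        "value": miss_frac[~keep_a],
    })

    g = g[keep_a]
    n_kept = g.shape[0]
    called = g != MISSING
    callrate = called.mean(axis=0) if n_kept else np.zeros(g.shape[1])
    n_bb = ((g == 2) & called).sum(axis=0)
    n_ab = ((g == 1) & called).sum(axis=0)
    n_aa = ((g == 0) & called).sum(axis=0)
    n_called = n_aa + n_ab + n_bb
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = np.where(n_called > 0, (2 * n_bb + n_ab) / (2 * n_called), 0.0)
    maf = np.minimum(freq_b, 1 - freq_b)

    reasons, values, drop = [], [], np.zeros(g.shape[1], dtype=bool)
    for j in range(g.shape[1]):
        if callrate[j] < marker_callrate_min:
            drop[j], r, v = True, "callrate", callrate[j]
        elif maf[j] <= maf_min:
            drop[j], r, v = True, "maf", maf[j]
        else:
            p = hwe_exact_test(int(n_aa[j]), int(n_ab[j]), int(n_bb[j]))
            if p < hwe_p_min:
                drop[j], r, v = True, "hwe", p
            else:
                continue
        reasons.append(r)
        values.append(v)
    removed_markers = pd.DataFrame({
        "marker_id": panel.markers.marker_ids[drop],
        "reason": reasons,
        "value": values,
    })
    out = panel.subset(animal_idx=np.flatnonzero(keep_a),
                       marker_idx=np.flatnonzero(~drop))
    return out, QCReport(removed_animals, removed_markers)


# ---------------------------------------------------------------------------
# Tabular inputs: pedigree, litters, LRR, EBV
# ---------------------------------------------------------------------------

def _toposort(ped: pd.DataFrame) -> list[str]:
    """Parents-before-offspring order; raises on pedigree cycles."""
    parents = {r.animal: [p for p in (r.sire, r.dam) if pd.notna(p) and p != ""]
               for r in ped.itertuples(index=False)}
    order: list[str] = []
    state: dict[str, int] = {}  # 1 = in stack, 2 = done

    for root in parents:
        if state.get(root):
            continue
        stack = [(root, iter(parents.get(root, [])))]
        state[root] = 1
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                st = state.get(p)
                if st == 1:
                    raise ValidationError(f"pedigree cycle involving {p}")
                if st is None:
                    state[p] = 1
                    stack.append((p, iter(parents.get(p, []))))
                    advanced = True
                    break
            if not advanced:
                state[node] = 2
                order.append(node)
                stack.pop()
    return order


def load_pedigree(path: str | Path) -> pd.DataFrame:
    ped = pd.read_csv(path, dtype={"animal": str, "sire": str, "dam": str})
    missing_cols = set(PEDIGREE_COLUMNS) - set(ped.columns)
    if missing_cols:
        raise ValidationError(f"pedigree missing columns {sorted(missing_cols)}")
    ped["birth_date"] = pd.to_datetime(ped["birth_date"])
    if ped["animal"].duplicated().any():
        raise ValidationError("duplicate animal in pedigree")
    _toposort(ped)  # raises on cycles
    known = set(ped["animal"])
    ped["is_founder"] = [
        (pd.isna(s) or s not in known) and (pd.isna(d) or d not in known)
        for s, d in zip(ped["sire"], ped["dam"])
    ]
    return ped


def load_litters(path: str | Path, mummies_in_tnb: bool = False) -> pd.DataFrame:
    lit = pd.read_csv(path, dtype={"litter_id": str, "sire": str, "dam": str,
                                   "farm": str})
    missing_cols = set(LITTER_COLUMNS) - set(lit.columns)
    if missing_cols:
        raise ValidationError(f"litter table missing columns {sorted(missing_cols)}")
    lit["date"] = pd.to_datetime(lit["date"])
    bad = lit["nba"] + lit["stillborn"] > lit["tnb"]
    if bad.any():
        ids = lit.loc[bad, "litter_id"].tolist()
        raise ValidationError(f"nba + stillborn > tnb for litters {ids}")
    if (lit[["tnb", "nba", "stillborn", "mummified", "parity"]] < 0).any().any():
        raise ValidationError("negative litter count")
    if (lit["parity"] < 1).any():
        raise ValidationError("parity must be >= 1")
    if mummies_in_tnb:
        lit = lit.assign(tnb=lit["tnb"] + lit["mummified"])
    return lit


def load_lrr(path: str | Path) -> pd.DataFrame:
    """LRR TSV: animals in rows (index column ``animal``), markers in columns."""
    lrr = pd.read_csv(path, sep="\t", dtype={"animal": str}).set_index("animal")
    return lrr.astype(float)


def load_ebv(path: str | Path) -> pd.DataFrame:
    ebv = pd.read_csv(path, dtype={"animal": str, "trait": str})
    missing_cols = set(EBV_COLUMNS) - set(ebv.columns)
    if missing_cols:
        raise ValidationError(f"EBV table missing columns {sorted(missing_cols)}")
    for col, lo, hi in [("rel", 0, 1), ("rel_pa", 0, 1), ("h2", 0, 1)]:
        if ((ebv[col] < lo) | (ebv[col] >= hi)).any():
            raise ValidationError(f"{col} outside [{lo}, {hi})")
    return ebv


def load_tables(pedigree_path, litters_path, lrr_path, ebv_path,
                mummies_in_tnb: bool = False):
    """Load the four tabular inputs; see the individual loaders for contracts."""
    return (load_pedigree(pedigree_path),
            load_litters(litters_path, mummies_in_tnb=mummies_in_tnb),
            load_lrr(lrr_path),
            load_ebv(ebv_path))
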