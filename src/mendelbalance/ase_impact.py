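"""Allele-specific expression testing and deletion transcript-impact prediction.

A deletion that removes cis-regulatory elements shifts the expression balance
between the two alleles at linked heterozygous coding sites; read counts at
such sites are tested against the 50:50 null with an exact two-sided binomial
test and Benjamini-Hochberg FDR correction.

A deletion that removes coding exons changes the mature transcript: skipped
exons are spliced out, and if the removed coding length is not a multiple of
three the downstream reading frame shifts, typically introducing a short run
of novel residues before a premature stop and truncating the protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from scipy import stats
from statsmodels.stats.multitest import multipletests

ASE_FDR_THRESHOLD = 0.05


@dataclass
class ASECount:
    locus: str          # "chrom:pos"
    gene: str
    del_allele: str     # base on the deletion haplotype
    alt_allele: str     # base on the wild-type haplotype
    del_count: int
    wt_count: int

    def __post_init__(self):
        if self.del_count < 0 or self.wt_count < 0:
            raise ValueError("negative read count")

    @property
    def total(self) -> int:
        return self.del_count + self.wt_count


@dataclass
class GeneModel:
    """Exon/CDS structure with per-exon forward-strand genomic sequence.

    ``exons`` are 1-based closed genomic intervals in ascending order;
    transcript orientation is ascending for '+' genes and descending (with
    reverse-complemented sequence) for '-' genes.  ``cds_start <= cds_end``
    in genomic coordinates; the start codon begins at cds_start on '+' and
    ends at cds_end on '-'.
    """

    gene: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    exon_seqs: list[str]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        for (s, e), seq in zip(self.exons, self.exon_seqs):
            if e < s or len(seq) != e - s + 1:
                raise ValueError(f"exon ({s},{e}) inconsistent with sequence")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap or are unsorted")


@dataclass
class TranscriptImpact:
    skipped_exons: list[int]        # indices into GeneModel.exons (0-based)
    frameshift: bool
    novel_aa: int
    protein_length_wt: int
    protein_length_mut: int
    partial_overlap: bool = False   # an exon only partly inside the deletion


# ---------------------------------------------------------------------------
# ASE testing
# ---------------------------------------------------------------------------

def ase_test(count: ASECount) -> tuple[float, float]:
    """(wild-type allele ratio, exact two-sided binomial p at p0 = 0.5).

    Ratio is wt_count / total; the p-value sums the probabilities of all
    outcomes no more likely than the observed one under Binomial(n, 0.5).
    """
    n = count.total
    if n == 0:
        raise ValueError(f"no reads at {count.locus}")
    ratio = count.wt_count / n
    p = stats.binomtest(count.wt_count, n, 0.5, alternative="two-sided").pvalue
    return float(ratio), float(p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ase_table(counts: list[ASECount],
              fdr_threshold: float = ASE_FDR_THRESHOLD):
    """Test every site and BH-adjust across the supplied set.

    Returns a list of dicts (locus, gene, ratio, raw_p, fdr_p, significant).
    """
    ratios_ps = [ase_test(c) for c in counts]
    fdr = bh_adjust([p for _, p in ratios_ps])
    return [{
        "locus": c.locus, "gene": c.gene,
        "del_count": c.del_count, "wt_count": c.wt_count,
        "ratio": r, "raw_p": p, "fdr_p": float(q),
        "significant": bool(q < fdr_threshold),
    } for c, (r, p), q in zip(counts, ratios_ps, fdr)]


# ---------------------------------------------------------------------------
# Transcript impact
# ---------------------------------------------------------------------------

def _transcript_order(model: GeneModel):
    idx = range(len(model.exons))
    return list(idx) if model.strand == "+" else list(idx)[::-1]


def _exon_tx_seq(model: GeneModel, i: int) -> str:
    seq = model.exon_seqs[i]
    return seq if model.strand == "+" else str(Seq(seq).reverse_complement())


def _genomic_to_tx(model: GeneModel, exon_order, pos: int) -> int | None:
    """Transcript offset (0-based) of a genomic position, or None if intronic."""
    off = 0
    for i in exon_order:
        s, e = model.exons[i]
        if s <= pos <= e:
            within = pos - s if model.strand == "+" else e - pos
            return off + within
        off += e - s + 1
    return None


def _protein_from(tx: str, start: int) -> str:
    """Residues from ``start`` to the first stop codon (stop excluded);
    translation stops at the transcript end if no stop is reached."""
    return str(Seq(tx[start:len(tx) - (len(tx) - start) % 3]).translate(to_stop=True))


def predict_deletion_transcript(model: GeneModel,
                                deletion: tuple[int, int]) -> TranscriptImpact:
    """Impact of a genomic deletion on the gene's transcript and protein.

    Any exon overlapping the (closed) deletion interval is removed; the
    remaining exons are spliced in transcript order and translation restarts
    from the original start codon, running to the first stop.  A deletion
    that removes the start codon is reported as complete loss
    (protein_length_mut = 0).
    """
    dlo, dhi = deletion
    if dhi < dlo:
        raise ValueError("empty deletion interval")
    order = _transcript_order(model)
    skipped = [i for i in order
               if model.exons[i][0] <= dhi and model.exons[i][1] >= dlo]
    partial = any(not (dlo <= model.exons[i][0] and model.exons[i][1] <= dhi)
                  for i in skipped)

    wt_tx = "".join(_exon_tx_seq(model, i) for i in order)
    start_pos = model.cds_start if model.strand == "+" else model.cds_end
    end_pos = model.cds_end if model.strand == "+" else model.cds_start
    tx_start = _genomic_to_tx(model, order, start_pos)
    tx_end = _genomic_to_tx(model, order, end_pos)
    if tx_start is None or tx_end is None:
        raise ValueError("CDS boundary falls outside all exons")
    wt_prot = _protein_from(wt_tx, tx_start)
    protein_length_wt = len(wt_prot)

    kept = [i for i in order if i not in skipped]
    mut_tx = "".join(_exon_tx_seq(model, i) for i in kept)

    # deleted coding length: overlap of each skipped exon with the wt CDS span
    cds_lo, cds_hi = sorted((tx_start, tx_end))
    deleted_coding = 0
    for i in skipped:
        s, e = model.exons[i]
        a = _genomic_to_tx(model, order, s if model.strand == "+" else e)
        b = a + (e - s)
        deleted_coding += max(0, min(b, cds_hi) - max(a, cds_lo) + 1)
    frameshift = deleted_coding % 3 != 0

    # locate the start codon in the mutant transcript
    start_exon = next((i for i in order
                       if model.exons[i][0] <= start_pos <= model.exons[i][1]),
                      None)
    if start_exon in skipped or start_exon is None:
        return TranscriptImpact(skipped, frameshift and bool(skipped), 0,
                                protein_length_wt, 0, partial)
    mut_start = _genomic_to_tx_kept(model, kept, start_pos)
    mut_prot = _protein_from(mut_tx, mut_start)
    if not skipped:
        return TranscriptImpact([], False, 0, protein_length_wt,
                                len(mut_prot), False)
    if frameshift:
        lcp = 0
        for a, b in zip(wt_prot, mut_prot):
            if a != b:
                break
            lcp += 1
        novel = len(mut_prot) - lcp
    else:
        novel = 0
    return TranscriptImpact(skipped, frameshift, novel, protein_length_wt,
                            len(mut_prot), partial)


def _genomic_to_tx_kept(model: GeneModel, kept, pos: int) -> int:
    off = 0
    for i in kept:
        s, e = model.exons[i]
        if s <= pos <= e:
            within = pos - s if model.strand == "+" else e - pos
            return off + within
        off += e - s + 1
    raise ValueError("position not in retained exons")
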