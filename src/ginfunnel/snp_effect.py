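"""Per-SNP genotype-group trait statistics, ORF-based mutation-consequence
classification, and the seven-class genetic-effect taxonomy.

The impact rate of a variant is (High group mean - Low group mean) / Low
group mean x 100%, High being whichever genotype group has the larger
trait mean (so the rate is always >= 0).

Dominance taxonomy (labels normalized so AA is the favorable homozygote,
i.e. the one with the larger trait mean):

    OD   het above the favorable homozygote (over-dominance)
    CD   het equal to the favorable homozygote (complete dominance)
    ID   het between the midpoint and the favorable homozygote
    AD   het at the homozygote midpoint (additive)
    NID  het between the unfavorable homozygote and the midpoint
    NCD  het equal to the unfavorable homozygote
    NOD  het below the unfavorable homozygote (negative over-dominance)

Sample means are never exactly equal, so equality is operationalized as
"not significantly different" (two-sample t for het vs either homozygote,
one-sample t of het values against the observed midpoint), checked outward
from the midpoint; an exact-arithmetic mode with a 1e-9 tolerance exists
for analytic tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from Bio.Seq import Seq
from scipy import stats

log = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")

EFFECT_CLASSES = ("OD", "CD", "ID", "AD", "NID", "NCD", "NOD")
MUTATION_CLASSES = ("synonymous", "non-synonymous", "frameshift", "outside-ORF")


@dataclass
class SnpTraitStat:
    snp: str
    gene: str
    mean_high: float
    mean_low: float
    group_sizes: tuple[int, int]
    t: float
    p: float
    impact_rate: float  # percent
    testable: bool


@dataclass
class MutationRecord:
    gene: str
    pos_in_mrna: int  # 1-based
    ref: str
    alt: str
    in_orf: bool
    mclass: str  # one of MUTATION_CLASSES


@dataclass
class GeneticEffectResult:
    m_favorable: float  # mean of the favorable homozygote ("AA")
    m_het: float
    m_unfavorable: float  # mean of the unfavorable homozygote ("GG")
    favorable_allele: str
    effect_class: str  # one of EFFECT_CLASSES
    het_vs_favorable_p: float


# ---------------------------------------------------------------------------
# Genotype-group t-test and impact rate


def impact_rate(mean_a: float, mean_b: float) -> float:
    """(High - Low) / Low x 100, High being the larger of the two means."""
    hi, lo = max(mean_a, mean_b), min(mean_a, mean_b)
    if lo == 0:
        return float("inf") if hi > 0 else 0.0
    return (hi - lo) / lo * 100.0


def snp_trait_test(
    genotypes_at_snp: np.ndarray,
    trait: np.ndarray,
    snp_id: str = "",
    gene_id: str = "",
    pool_het_with_minor: bool = False,
) -> SnpTraitStat:
    """Equal-variance two-sample t-test between the two homozygote groups.

    Heterozygotes are excluded by default; ``pool_het_with_minor`` pools
    them with the smaller homozygote group instead.  A group with fewer
    than 2 members makes the SNP untestable (flagged, p = NaN).
    """
    g = np.asarray(genotypes_at_snp)
    y = np.asarray(trait, dtype=float)
    a = y[g == 0]
    b = y[g == 2]
    if pool_het_with_minor:
        het = y[g == 1]
        if a.size <= b.size:
            a = np.concatenate([a, het])
        else:
            b = np.concatenate([b, het])
    if a.size < 2 or b.size < 2:
        return SnpTraitStat(snp_id, gene_id, float("nan"), float("nan"),
                            (a.size, b.size), float("nan"), float("nan"),
                            float("nan"), testable=False)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    ma, mb = float(a.mean()), float(b.mean())
    hi, lo = max(ma, mb), min(ma, mb)
    if np.isnan(t):  # identical values in both groups
        t, p = 0.0, 1.0
    return SnpTraitStat(snp_id, gene_id, hi, lo, (a.size, b.size),
                        float(t), float(p), impact_rate(ma, mb), testable=True)


def significant_snp_summary(stats_list: list[SnpTraitStat], alpha: float = 0.05,
                            mutations: list[MutationRecord] | None = None) -> dict:
    """Counts and percentages of significant SNPs and consequence classes.

    Percentages are 100 * part / whole rounded to one decimal place.
    """
    def pct(part: int, whole: int) -> float:
        return round(100.0 * part / whole, 1) if whole else 0.0

    testable = [s for s in stats_list if s.testable]
    sig = [s for s in testable if s.p <= alpha]
    out = {
        "n_snps": len(stats_list),
        "n_testable": len(testable),
        "n_significant": len(sig),
        "pct_significant": pct(len(sig), len(stats_list)),
    }
    if mutations is not None:
        in_orf = [m for m in mutations if m.in_orf]
        out["n_in_orf"] = len(in_orf)
        out["n_outside_orf"] = len(mutations) - len(in_orf)
        for cls in ("synonymous", "non-synonymous", "frameshift"):
            n = sum(1 for m in in_orf if m.mclass == cls)
            out[f"n_{cls}"] = n
            out[f"pct_{cls}"] = pct(n, len(in_orf))
    return out


# ---------------------------------------------------------------------------
# ORF finding and mutation classification


def find_orf(mrna_sequence: str, min_len: int = 150) -> tuple[int, int] | None:
    """Longest ATG-initiated, stop-terminated forward-frame ORF >= min_len nt.

    Coordinates are 1-based inclusive and include the stop codon; returns
    None when no qualifying ORF exists.  Ties on length resolve to the
    earliest start.
    """
    seq = mrna_sequence.upper()
    if set(seq) - VALID_BASES:
        raise ValueError("sequence contains non-nucleotide characters")
    best: tuple[int, int] | None = None
    best_len = 0
    for frame in range(3):
        i = frame
        while i + 3 <= len(seq):
            if seq[i : i + 3] == "ATG":
                j = i + 3
                while j + 3 <= len(seq):
                    if seq[j : j + 3] in {"TAA", "TAG", "TGA"}:
                        length = j + 3 - i
                        if length >= min_len and (length > best_len or (length == best_len and best and i + 1 < best[0])):
                            best = (i + 1, j + 3)
                            best_len = length
                        break
                    j += 3
            i += 3
    return best


def classify_mutation(
    gene_id: str,
    mrna_sequence: str,
    orf: tuple[int, int] | None,
    pos_in_mrna: int,
    ref: str,
    alt: str,
) -> MutationRecord:
    """Classify a substitution or InDel on an oriented mRNA.

    Outside the ORF -> outside-ORF.  A substitution in the ORF is
    translated before/after with the standard genetic code (synonymous vs
    non-synonymous).  An InDel in the ORF is a frameshift when the length
    difference is not a multiple of 3, otherwise in-frame and reported as
    non-synonymous.
    """
    seq = mrna_sequence.upper()
    ref, alt = ref.upper(), alt.upper()
    if not (1 <= pos_in_mrna <= len(seq)):
        raise ValueError(f"position {pos_in_mrna} outside mRNA of length {len(seq)}")
    if seq[pos_in_mrna - 1 : pos_in_mrna - 1 + len(ref)] != ref:
        raise ValueError(
            f"{gene_id}: reference allele {ref!r} does not match mRNA at {pos_in_mrna}"
        )
    in_orf = orf is not None and orf[0] <= pos_in_mrna <= orf[1]
    if not in_orf:
        return MutationRecord(gene_id, pos_in_mrna, ref, alt, False, "outside-ORF")
    if len(ref) != len(alt):
        shift = abs(len(ref) - len(alt)) % 3 != 0
        cls = "frameshift" if shift else "non-synonymous"
        return MutationRecord(gene_id, pos_in_mrna, ref, alt, True, cls)
    # substitution: translate the affected codon(s)
    start = orf[0] - 1
    offset = pos_in_mrna - 1 - start
    codon_start = start + (offset // 3) * 3
    n_codons = (offset % 3 + len(ref) + 2) // 3
    before = seq[codon_start : codon_start + 3 * n_codons]
    mutated = seq[: pos_in_mrna - 1] + alt + seq[pos_in_mrna - 1 + len(ref) :]
    after = mutated[codon_start : codon_start + 3 * n_codons]
    aa_before = str(Seq(before).translate())
    aa_after = str(Seq(after).translate())
    cls = "synonymous" if aa_before == aa_after else "non-synonymous"
    return MutationRecord(gene_id, pos_in_mrna, ref, alt, True, cls)


# ---------------------------------------------------------------------------
# Seven-class genetic-effect taxonomy


def _exact_eq(tolerance: float = 1e-9):
    def eq(values_a: np.ndarray, target: float) -> bool:
        return abs(float(np.mean(values_a)) - target) <= tolerance
    return eq


def classify_genetic_effect(
    hom1_values: np.ndarray,
    het_values: np.ndarray,
    hom2_values: np.ndarray,
    hom1_allele: str = "A",
    hom2_allele: str = "G",
    equality: Literal["ttest", "exact"] = "ttest",
    alpha: float = 0.05,
    tolerance: float = 1e-9,
) -> GeneticEffectResult:
    """Assign one of the seven dominance classes to a three-genotype SNP.

    Group labels are normalized so "AA" denotes the favorable homozygote
    (larger trait mean).  With ``equality="ttest"``, AG=AA and AG=GG use a
    two-sample t-test and AG=midpoint a one-sample t-test of the het values
    against the observed midpoint, all at ``alpha``; equalities are checked
    outward from the midpoint, strict inequalities apply otherwise.  With
    ``equality="exact"`` the comparisons are plain arithmetic within
    ``tolerance`` (for analytic fixtures).
    """
    a = np.asarray(hom1_values, dtype=float)
    h = np.asarray(het_values, dtype=float)
    g = np.asarray(hom2_values, dtype=float)
    if a.size == 0 or h.size == 0 or g.size == 0:
        raise ValueError("two-genotype SNP, effect analysis impossible")
    # normalize: favorable homozygote first
    if a.mean() >= g.mean():
        fav, fav_allele, unf = a, hom1_allele, g
    else:
        fav, fav_allele, unf = g, hom2_allele, a
    m_fav, m_het, m_unf = float(fav.mean()), float(h.mean()), float(unf.mean())
    mid = (m_fav + m_unf) / 2.0

    if equality == "exact":
        eq_fav = abs(m_het - m_fav) <= tolerance
        eq_unf = abs(m_het - m_unf) <= tolerance
        eq_mid = abs(m_het - mid) <= tolerance
    elif equality == "ttest":
        eq_fav = _groups_equal(h, fav, alpha)
        eq_unf = _groups_equal(h, unf, alpha)
        eq_mid = _mean_equals(h, mid, alpha)
    else:
        raise ValueError(f"unknown equality mode {equality!r}")

    # checked outward from the midpoint
    if eq_mid:
        cls = "AD"
    elif m_het > mid:
        if eq_fav:
            cls = "CD"
        elif m_het > m_fav:
            cls = "OD"
        else:
            cls = "ID"
    else:
        if eq_unf:
            cls = "NCD"
        elif m_het < m_unf:
            cls = "NOD"
        else:
            cls = "NID"

    _t, p = stats.ttest_ind(h, fav, equal_var=True) if h.size > 1 and fav.size > 1 else (0.0, 1.0)
    if np.isnan(p):
        p = 1.0
    return GeneticEffectResult(
        m_favorable=m_fav, m_het=m_het, m_unfavorable=m_unf,
        favorable_allele=fav_allele, effect_class=cls, het_vs_favorable_p=float(p),
    )


def _groups_equal(x: np.ndarray, y: np.ndarray, alpha: float) -> bool:
    if x.size < 2 or y.size < 2:
        return False
    t, p = stats.ttest_ind(x, y, equal_var=True)
    if np.isnan(p):
        return True  # zero-variance identical groups
    return p > alpha


def _mean_equals(x: np.ndarray, target: float, alpha: float) -> bool:
    if x.size < 2:
        return False
    if x.std(ddof=1) == 0:
        return abs(float(x.mean()) - target) <= 1e-12
    _t, p = stats.ttest_1samp(x, target)
    return p > alpha
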