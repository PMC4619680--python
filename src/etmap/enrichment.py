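"""Candidate-gene recovery and hypergeometric enrichment.

GWAS hits are ranked by p-value (ties broken by chromosome and position),
the top L SNPs (default 2000) are assigned to the gene(s) overlapping their
position or, for non-genic SNPs, to the closest gene (equidistant ties keep
both).  Walking down the ranked list, each newly seen gene increments the
count m of unique genes evaluated; recoveries of genes from a known
candidate list increment k.  Enrichment at each step is the exact
hypergeometric upper tail P(X >= k) for K known genes among N assignable
genes, computed in log space.  Permutation envelopes rerun the whole scan on
jointly permuted traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .io_core import GeneAnnotation

__all__ = [
    "assign_snp_to_genes",
    "rank_snps",
    "CandidateList",
    "RecoveryCurve",
    "recovery_curve",
    "hypergeom_tail",
    "PermutationEnvelope",
    "permutation_envelope",
    "assignable_genes",
]


def assign_snp_to_genes(
    chrom: str, pos: int, annotation: GeneAnnotation, window: int | None = None
) -> list[str]:
    """Genes containing the SNP, else the nearest gene(s) on the chromosome.

    Distance to a gene is max(start - pos, pos - end, 0); equidistant
    nearest genes are both returned.  A chromosome absent from the
    annotation yields an empty list (unassigned).  With ``window`` set,
    assignment switches to all genes within that many bp of the SNP
    (a comparison mode, not the default).
    """
    t = annotation.table
    sub = t[t["chrom"] == str(chrom)]
    if sub.empty:
        return []
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    dist = np.maximum(starts - pos, 0) + np.maximum(pos - ends, 0)
    if window is not None:
        return sub["gene_id"].to_numpy()[dist <= window].tolist()
    hit = dist == 0
    if hit.any():
        return sub["gene_id"].to_numpy()[hit].tolist()
    dmin = dist.min()
    return sub["gene_id"].to_numpy()[dist == dmin].tolist()


def rank_snps(results: pd.DataFrame, p_col: str, top: int = 2000) -> pd.DataFrame:
    """Sort SNPs by ascending p, ties broken by (chrom, pos); keep top L."""
    out = results.sort_values([p_col, "chrom", "pos"], kind="mergesort")
    return out.head(top).reset_index(drop=True)


@dataclass
class CandidateList:
    """Ranked candidate SNPs with their assigned gene ids."""

    snps: pd.DataFrame  # snp_id, chrom, pos, p
    genes: list[list[str]]  # parallel to snps rows

    def __len__(self) -> int:
        return len(self.snps)


def build_candidates(
    results: pd.DataFrame, annotation: GeneAnnotation, p_col: str = "p", top: int = 2000
) -> CandidateList:
    ranked = rank_snps(results, p_col, top)
    genes = [
        assign_snp_to_genes(c, p, annotation)
        for c, p in zip(ranked["chrom"], ranked["pos"])
    ]
    return CandidateList(snps=ranked[["snp_id", "chrom", "pos", p_col]], genes=genes)


def assignable_genes(annotation: GeneAnnotation, snp_chrom, snp_pos) -> set[str]:
    """Unique genes assignable from a full SNP panel (the N of the tail)."""
    out: set[str] = set()
    for c, p in zip(snp_chrom, snp_pos):
        out.update(assign_snp_to_genes(c, int(p), annotation))
    return out


def hypergeom_tail(k: int, m: int, K_known: int, N_total: int) -> float:
    """Exact upper tail P(X >= k), X ~ Hypergeometric(N_total, K_known, m).

    Summed in log space for stability far into the tail.
    """
    if not (0 <= k <= m <= N_total) or k > K_known or K_known <= 0 or N_total < K_known:
        raise ValueError(f"invalid hypergeometric arguments k={k} m={m} K={K_known} N={N_total}")
    if k == 0:
        return 1.0
    hi = min(m, K_known)
    lo = max(0, m - (N_total - K_known))
    if k > hi:
        return 0.0
    if k <= lo:  # the whole support lies at or above k
        return 1.0
    # sum the smaller side in log space; when the upper tail is the large
    # side, 1 - lower-sum keeps full relative precision
    upper = np.arange(k, hi + 1)
    lower = np.arange(lo, k)
    log_upper = logsumexp(hypergeom.logpmf(upper, N_total, K_known, m))
    if len(lower) == 0 or log_upper <= np.log(0.5):
        return float(min(1.0, np.exp(log_upper)))
    log_lower = logsumexp(hypergeom.logpmf(lower, N_total, K_known, m))
    return float(min(1.0, 1.0 - np.exp(log_lower)))


@dataclass
class RecoveryCurve:
    """Per newly evaluated gene: cumulative recovery and enrichment."""

    table: pd.DataFrame  # m, gene_id, known, k, p_enrich
    K_known: int
    N_total: int

    def k_at(self, m_grid: np.ndarray) -> np.ndarray:
        """Step-function evaluation of k at arbitrary m values."""
        m = self.table["m"].to_numpy()
        k = self.table["k"].to_numpy()
        idx = np.searchsorted(m, m_grid, side="right") - 1
        out = np.where(idx >= 0, k[np.clip(idx, 0, len(k) - 1)], 0)
        return out


def recovery_curve(
    candidates: CandidateList, known_genes, K_known: int, N_total: int
) -> RecoveryCurve:
    """Walk ranked SNPs; every newly seen gene adds an evaluation step."""
    if K_known <= 0 or N_total < K_known:
        raise ValueError("need 0 < K_known <= N_total")
    known = set(known_genes)
    seen: set[str] = set()
    rows = []
    m = k = 0
    for genes in candidates.genes:
        for gid in genes:
            if gid in seen:
                continue
            seen.add(gid)
            m += 1
            hit = gid in known
            if hit:
                k += 1
            rows.append((m, gid, hit, k, hypergeom_tail(k, m, K_known, N_total)))
    return RecoveryCurve(
        table=pd.DataFrame(rows, columns=["m", "gene_id", "known", "k", "p_enrich"]),
        K_known=K_known, N_total=N_total,
    )


@dataclass
class PermutationEnvelope:
    """5th/95th percentiles of k per m over trait permutations."""

    m_grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_perm: int


def permutation_envelope(
    gwas_runner,
    traits: np.ndarray,
    annotation: GeneAnnotation,
    known_genes,
    K_known: int,
    N_total: int,
    n_perm: int = 200,
    seed: int = 0,
    top: int = 2000,
    p_col: str = "p",
    m_max: int | None = None,
) -> PermutationEnvelope:
    """Null envelope of the recovery curve under joint trait permutation.

    ``gwas_runner(traits_permuted)`` must return a results DataFrame with
    snp_id/chrom/pos and the ranked p column.  Trait columns are permuted
    jointly across accessions (rows stay together); kinship is untouched.
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    traits = np.asarray(traits, dtype=float)
    if traits.ndim == 1:
        traits = traits[:, None]
    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(n_perm):
        perm = rng.permutation(traits.shape[0])
        res = gwas_runner(traits[perm])
        cand = build_candidates(res, annotation, p_col=p_col, top=top)
        curves.append(recovery_curve(cand, known_genes, K_known, N_total))
    if m_max is None:
        m_max = max(int(c.table["m"].max()) for c in curves if len(c.table))
    m_grid = np.arange(1, m_max + 1)
    ks = np.stack([c.k_at(m_grid) for c in curves])
    return PermutationEnvelope(
        m_grid=m_grid,
        lower=np.percentile(ks, 5, axis=0),
        upper=np.percentile(ks, 95, axis=0),
        n_perm=n_perm,
    )
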