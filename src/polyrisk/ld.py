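"""Linkage-disequilibrium estimation and block pruning.

r-squared between two SNPs is the composite (genotype-dosage) estimator:
the squared Pearson correlation of the two dosage vectors over samples
non-missing at both SNPs.  It is phase-free and deterministic, and it
coincides with the haplotype r-squared whenever phase is unambiguous.

An LD block is a connected component of the graph whose edges join SNP
pairs with r-squared at or above the threshold (0.5 = "moderate to strong"
by convention here).  Pruning keeps, per block, the SNP most strongly
associated with disease (smallest p, ties by larger |beta| then genomic
position).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from polyrisk.association import AssocResult
from polyrisk.genotype_io import GenotypeMatrix

__all__ = ["LdMatrix", "pairwise_r2", "ld_matrix", "ld_blocks", "prune_by_ld", "PruneRecord"]


@dataclass
class LdMatrix:
    """Symmetric pairwise r-squared matrix with pairwise-complete counts."""

    snp_ids: list[str]
    r2: np.ndarray
    n_pairs_used: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.snp_ids)
        if self.r2.shape != (m, m) or self.n_pairs_used.shape != (m, m):
            raise ValueError("matrix shapes inconsistent with snp_ids")

    def value(self, a: str, b: str) -> float:
        i, j = self.snp_ids.index(a), self.snp_ids.index(b)
        return float(self.r2[i, j])

    def subset(self, snp_ids: Sequence[str]) -> "LdMatrix":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return LdMatrix(
            list(snp_ids), self.r2[np.ix_(idx, idx)], self.n_pairs_used[np.ix_(idx, idx)]
        )


def pairwise_r2(gm: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Composite r-squared between two SNPs; NaN if either is monomorphic
    in the pairwise-complete subset."""
    ga, gb = gm.column(snp_a), gm.column(snp_b)
    keep = ~np.isnan(ga) & ~np.isnan(gb)
    a, b = ga[keep], gb[keep]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_matrix(gm: GenotypeMatrix, snp_ids: Sequence[str] | None = None) -> LdMatrix:
    """All pairwise r-squared values for the given SNPs (default: all)."""
    ids = list(snp_ids) if snp_ids is not None else gm.snp_ids
    m = len(ids)
    r2 = np.eye(m)
    n_used = np.zeros((m, m), dtype=int)
    cols = [gm.column(s) for s in ids]
    for i in range(m):
        n_used[i, i] = int((~np.isnan(cols[i])).sum())
        mono = np.ptp(cols[i][~np.isnan(cols[i])]) == 0 if n_used[i, i] else True
        if mono:
            r2[i, i] = np.nan
        for j in range(i + 1, m):
            keep = ~np.isnan(cols[i]) & ~np.isnan(cols[j])
            n_used[i, j] = n_used[j, i] = int(keep.sum())
            r2[i, j] = r2[j, i] = pairwise_r2(gm, ids[i], ids[j])
    return LdMatrix(ids, r2, n_used)


def ld_blocks(ld: LdMatrix, threshold: float = 0.5) -> list[list[str]]:
    """Partition SNPs into LD blocks: connected components of the
    r-squared >= threshold graph.  Singletons allowed.  Blocks are returned
    in order of each block's first SNP in the input ordering."""
    g = nx.Graph()
    g.add_nodes_from(ld.snp_ids)
    m = len(ld.snp_ids)
    for i in range(m):
        for j in range(i + 1, m):
            v = ld.r2[i, j]
            if np.isfinite(v) and v >= threshold:
                g.add_edge(ld.snp_ids[i], ld.snp_ids[j])
    order = {s: k for k, s in enumerate(ld.snp_ids)}
    blocks = [sorted(c, key=order.__getitem__) for c in nx.connected_components(g)]
    blocks.sort(key=lambda b: order[b[0]])
    return blocks


@dataclass
class PruneRecord:
    """One removed SNP: which block it belonged to and which SNP survives."""

    removed_snp: str
    block_id: int
    kept_snp: str
    r2_to_kept: float


def prune_by_ld(
    candidates: Sequence[AssocResult],
    ld: LdMatrix,
    gm: GenotypeMatrix,
    threshold: float = 0.5,
) -> tuple[list[str], list[PruneRecord]]:
    """Keep, per LD block, the single most strongly associated SNP.

    Selection within a block: smallest association p; ties broken by larger
    |beta|, then by (chrom, pos) ascending.  Returns the kept SNP ids (in
    the candidates' original order) and a log of removals.
    """
    by_id = {r.snp_id: r for r in candidates}
    missing = [s for s in by_id if s not in ld.snp_ids]
    if missing:
        raise KeyError(f"candidates absent from LD matrix: {missing}")
    sub = ld.subset([r.snp_id for r in candidates])
    pos = {s.snp_id: (s.chrom, s.pos) for s in gm.snps}

    def rank(snp_id: str):
        r = by_id[snp_id]
        p = r.p if np.isfinite(r.p) else np.inf
        b = abs(r.beta) if np.isfinite(r.beta) else 0.0
        return (p, -b, pos.get(snp_id, ("", 0)))

    kept: list[str] = []
    log: list[PruneRecord] = []
    for block_id, block in enumerate(ld_blocks(sub, threshold)):
        winner = min(block, key=rank)
        kept.append(winner)
        for s in block:
            if s != winner:
                log.append(PruneRecord(s, block_id, winner, sub.value(s, winner)))
    order = {r.snp_id: k for k, r in enumerate(candidates)}
    kept.sort(key=order.__getitem__)
    return kept, log
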