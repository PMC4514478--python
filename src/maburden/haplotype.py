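"""LD blocks within a 200 kb window and representative-SNP selection.

SNPs are grouped into blocks by a greedy left-to-right agglomeration: a SNP
joins the current block when it lies within the window of the block's first
SNP and its genotype r-squared with at least one current member reaches the
merge threshold.  LD is measured as composite (genotype-correlation)
r-squared — the squared Pearson correlation of copy counts — a deterministic
proxy for phased haplotype r-squared that requires no EM phasing.

Each block then contributes at most one representative SNP to the haplotype
risk model: the member with the smallest association p-value among those
meeting the model's MAF ceiling and p threshold; blocks with no qualifying
member contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, MISSING
from .stats import AssociationTable, MinorAlleleSet


@dataclass
class HaplotypeBlock:
    chrom: str
    snp_ids: list[str]
    span_bp: int
    representative: str | None = None

    @property
    def n_members(self) -> int:
        return len(self.snp_ids)


def pairwise_r2(gA: np.ndarray, gB: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of copy counts.

    Samples missing at either SNP are dropped.  Returns NaN (flagged
    undefined) when fewer than two complete pairs remain or either SNP is
    monomorphic among them.  Invariant to flipping either SNP's counted
    allele, since correlation is squared.
    """
    gA = np.asarray(gA, dtype=np.float64)
    gB = np.asarray(gB, dtype=np.float64)
    ok = (gA != MISSING) & (gB != MISSING)
    a, b = gA[ok], gB[ok]
    if len(a) < 2 or a.var() == 0 or b.var() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def build_blocks(matrix: GenotypeMatrix, window_bp: int = 200_000,
                 r2_min: float = 0.5) -> list[HaplotypeBlock]:
    """Greedy agglomerative LD blocks; every SNP lands in exactly one block.

    Within each chromosome (variants must be position-sorted), the current
    block absorbs the next SNP iff its distance to the block's first SNP is
    at most ``window_bp`` and its maximum r-squared with any current member
    is at least ``r2_min``; otherwise a new block starts.  Singletons are
    allowed, so blocks always partition the panel.
    """
    var = matrix.variants
    blocks: list[HaplotypeBlock] = []
    for chrom in var["chrom"].unique():
        idx = np.flatnonzero((var["chrom"] == chrom).to_numpy())
        pos = var["pos"].to_numpy()[idx]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"variants on chromosome {chrom} are not position-sorted")
        cur: list[int] = []
        start_pos = None
        for j in idx:
            pj = var["pos"].iloc[j]
            if cur and pj - start_pos <= window_bp:
                best = max(pairwise_r2(matrix.calls[:, k], matrix.calls[:, j])
                           for k in cur)
                if not np.isnan(best) and best >= r2_min:
                    cur.append(j)
                    continue
            if cur:
                blocks.append(_finish_block(var, cur))
            cur = [j]
            start_pos = pj
        if cur:
            blocks.append(_finish_block(var, cur))
    return blocks


def _finish_block(var: pd.DataFrame, members: list[int]) -> HaplotypeBlock:
    pos = var["pos"].iloc[members]
    return HaplotypeBlock(
        chrom=str(var["chrom"].iloc[members[0]]),
        snp_ids=list(var["snp_id"].iloc[members]),
        span_bp=int(pos.max() - pos.min()),
    )


def select_representatives(blocks: list[HaplotypeBlock],
                           association: AssociationTable,
                           ma_set: MinorAlleleSet,
                           maf_ceiling: float = 0.4,
                           p_threshold: float = 0.05) -> list[str]:
    """Pick each block's best-associated qualifying SNP.

    Qualification: converged fit, informative, control MAF < ceiling and
    p < threshold (both strict).  Ties on p break to the smaller bp
    position, encoded here by the earlier map order within the block.
    Blocks with no qualifying member are skipped.  The chosen id is also
    recorded on each block's ``representative`` field.
    """
    tab = association.table.set_index("snp_id")
    informative = pd.Series(ma_set.informative,
                            index=ma_set.table["snp_id"].to_numpy())
    chosen: list[str] = []
    for block in blocks:
        best_id, best_p = None, None
        for sid in block.snp_ids:  # map order == position order -> tie rule
            if sid not in tab.index or not informative.get(sid, False):
                continue
            row = tab.loc[sid]
            if not bool(row["converged"]):
                continue
            if not (row["control_maf"] < maf_ceiling and row["p_value"] < p_threshold):
                continue
            if best_p is None or row["p_value"] < best_p:
                best_id, best_p = sid, row["p_value"]
        block.representative = best_id
        if best_id is not None:
            chosen.append(best_id)
    return chosen


def blocks_to_frame(blocks: list[HaplotypeBlock]) -> pd.DataFrame:
    """Tabular export: chrom, n_members, span and representative per block."""
    return pd.DataFrame(
        [(b.chrom, b.snp_ids[0], b.snp_ids[-1], b.n_members, b.span_bp,
          b.representative if b.representative is not None else "")
         for b in blocks],
        columns=["chrom", "first_snp", "last_snp", "n_members", "span_bp",
                 "representative"],
    )
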