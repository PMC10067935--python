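"""SNP-to-gene mapping: the E/T/C/P evidence cascade and set bookkeeping.

Each association SNP is linked to candidate genes through up to three
independent evidence tables — eQTL targets (E-Genes), regulatory-element
targets (T-Genes) and coding consequences (C-Genes). The three lookups are
not exclusive: one SNP may contribute E, T and C assignments at once. Only a
SNP with *no* E/T/C hit falls back to its closest gene (P-Gene), so P is
exclusive by construction. Genes are treated as equal entities regardless of
evidence class.

Coordinates are 1-based and fully closed throughout, matching the printed
endpoints of the major-histocompatibility exclusion window on chromosome 6
(28,014,374-33,683,352), which is removed before mapping because of its
extreme linkage disequilibrium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from ._errors import IntegrityError

logger = logging.getLogger(__name__)

__all__ = [
    "HLA_WINDOW",
    "GeneAssignment",
    "AncestryGeneSets",
    "exclude_hla",
    "assign_evidence_genes",
    "assign_proximal",
    "partition_by_ancestry",
    "overlap_report",
    "random_gene_cohort",
    "filter_deg_table",
]

#: chromosome, first and last excluded base (1-based, closed)
HLA_WINDOW: tuple[str, int, int] = ("6", 28014374, 33683352)

ASSIGNMENT_COLUMNS = ["snp_id", "gene", "evidence", "source", "ancestries"]


@dataclass(frozen=True)
class GeneAssignment:
    snp_id: str
    gene: str
    evidence: str  # E, T, C or P
    source: str
    ancestries: str  # comma-joined sorted ancestry labels


def exclude_hla(snps: pd.DataFrame, window: tuple[str, int, int] = HLA_WINDOW) -> pd.DataFrame:
    """Drop SNPs inside the closed exclusion window; logs the removal count."""
    chrom, start, end = window
    mask = (snps["chrom"].astype(str) == str(chrom)) & (snps["pos"] >= start) & (snps["pos"] <= end)
    removed = int(mask.sum())
    logger.info("excluded %d SNP rows in window chr%s:%d-%d", removed, chrom, start, end)
    return snps.loc[~mask].reset_index(drop=True)


def _lookup_assignments(snps: pd.DataFrame, table: pd.DataFrame, evidence: str, source: str) -> pd.DataFrame:
    anc = (
        snps.groupby("snp_id")["ancestry"]
        .agg(lambda s: ",".join(sorted(set(s))))
        .rename("ancestries")
    )
    hits = table.merge(anc, left_on="snp_id", right_index=True, how="inner")
    out = hits[["snp_id", "gene", "ancestries"]].copy()
    out["evidence"] = evidence
    out["source"] = source
    return out[ASSIGNMENT_COLUMNS].drop_duplicates(["snp_id", "gene", "evidence"])


def assign_evidence_genes(
    snps: pd.DataFrame,
    eqtl_table: pd.DataFrame,
    regulatory_table: pd.DataFrame,
    coding_table: pd.DataFrame,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Emit E, T and C assignments; the three lookups are independent.

    ``universe``, when given, is the declared gene universe: a lookup row
    naming a gene outside it is a referential-integrity error.
    """
    parts = [
        _lookup_assignments(snps, eqtl_table, "E", "eqtl"),
        _lookup_assignments(snps, regulatory_table, "T", "regulatory"),
        _lookup_assignments(snps, coding_table, "C", "coding"),
    ]
    out = pd.concat(parts, ignore_index=True)
    if universe is not None:
        bad = sorted(set(out["gene"]) - universe)
        if bad:
            raise IntegrityError(f"lookup genes absent from the declared universe: {bad[:10]} (n={len(bad)})")
    return out.sort_values(["evidence", "snp_id", "gene"], kind="stable").reset_index(drop=True)


def assign_proximal(unassigned_snps: pd.DataFrame, gene_coords: pd.DataFrame) -> pd.DataFrame:
    """Assign each leftover SNP to its single closest gene (P evidence).

    Distance is 0 inside a gene's closed interval, otherwise the smaller gap
    to either interval end; ties break lexicographically by gene symbol.
    """
    if len(gene_coords) == 0:
        raise ValueError("gene coordinate table is empty")
    uniq = unassigned_snps.drop_duplicates("snp_id")
    anc = (
        unassigned_snps.groupby("snp_id")["ancestry"]
        .agg(lambda s: ",".join(sorted(set(s))))
    )
    rows = []
    for chrom, snp_grp in uniq.groupby(uniq["chrom"].astype(str), sort=True):
        genes = gene_coords.loc[gene_coords["chrom"].astype(str) == chrom]
        if len(genes) == 0:
            missing = snp_grp["snp_id"].tolist()
            raise ValueError(f"no genes on chromosome {chrom} for SNPs {missing[:5]}")
        genes = genes.sort_values("gene", kind="stable")  # lexicographic tie-break via argmin
        start = genes["start"].to_numpy()
        end = genes["end"].to_numpy()
        pos = snp_grp["pos"].to_numpy()[:, None]
        dist = np.where(
            (pos >= start[None, :]) & (pos <= end[None, :]),
            0,
            np.minimum(np.abs(pos - start[None, :]), np.abs(pos - end[None, :])),
        )
        best = dist.argmin(axis=1)
        for (snp_id, _), gi in zip(snp_grp[["snp_id", "pos"]].itertuples(index=False), best):
            rows.append((snp_id, genes["gene"].iloc[gi], "P", "proximal", anc[snp_id]))
    out = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    return out.sort_values(["snp_id"], kind="stable").reset_index(drop=True)


@dataclass
class AncestryGeneSets:
    """Per-ancestry gene sets plus the trans-ancestral (shared) set."""

    ancestries: dict[str, set[str]]
    shared: set[str]
    specific: dict[str, set[str]] = field(default_factory=dict)
    by_class: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for s in self.ancestries.values():
            out |= s
        return out


def partition_by_ancestry(assignments: pd.DataFrame) -> AncestryGeneSets:
    """Split genes into ancestry-specific and shared groups.

    A gene is *shared* iff SNPs linking to it (any evidence class) cover at
    least two ancestry labels between them; with two cohorts this is exactly
    the intersection of the per-ancestry gene sets.
    """
    per_anc: dict[str, set[str]] = {}
    per_class: dict[str, dict[str, set[str]]] = {}
    for row in assignments.itertuples(index=False):
        for anc in str(row.ancestries).split(","):
            per_anc.setdefault(anc, set()).add(row.gene)
            per_class.setdefault(anc, {}).setdefault(row.evidence, set()).add(row.gene)
    labels = sorted(per_anc)
    shared: set[str] = set.intersection(*per_anc.values()) if len(labels) >= 2 else set()
    specific = {a: per_anc[a] - shared for a in labels}
    return AncestryGeneSets(ancestries=per_anc, shared=shared, specific=specific, by_class=per_class)


def overlap_report(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Counts for every region of the n-set Venn partition.

    Region membership is exact (in all named sets, in none of the others);
    the counts therefore sum to the union size, which is asserted.
    """
    if len(sets) < 2:
        raise ValueError("overlap_report needs at least 2 sets")
    names = sorted(sets)
    union = set().union(*sets.values())
    rows = []
    total = 0
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo)) if r < len(names) else set()
            count = len(inside - outside)
            total += count
            rows.append({"region": "&".join(combo), "n_sets": r, "count": count})
    assert total == len(union), "Venn region counts must sum to the union size"
    out = pd.DataFrame(rows)
    out.attrs["union_size"] = len(union)
    return out


def random_gene_cohort(universe, n: int, seed: int) -> list[str]:
    """Uniform sample of ``n`` genes without replacement, reproducible by seed."""
    pool = sorted(universe)
    if n > len(pool):
        raise ValueError(f"cannot sample {n} genes from a universe of {len(pool)}")
    rng = np.random.default_rng(seed)
    return sorted(rng.choice(pool, size=n, replace=False).tolist())


def filter_deg_table(deg_table: pd.DataFrame, fdr_threshold: float = 0.2) -> list[str]:
    """Ingestion filter for differential-expression results.

    Keeps probes with FDR strictly below the threshold, then retains only the
    most significant probe (smallest p, ties by probe label) per gene.
    Returns the deduplicated gene list, sorted.
    """
    required = {"probe", "gene", "p", "fdr"}
    missing = required - set(deg_table.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    kept = deg_table.loc[deg_table["fdr"] < fdr_threshold]
    kept = kept.sort_values(["gene", "p", "probe"], kind="stable").drop_duplicates("gene", keep="first")
    return sorted(kept["gene"].tolist())
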