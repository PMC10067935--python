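"""Genomic functional categories for SNPs and ancestry proportion tests.

Every SNP arrives with a single controlled-vocabulary consequence term (the
kind of annotation a variant-effect predictor emits). The term determines a
functional *category* (intron, enhancer, missense, ...) and the category
determines a *super-group*:

- ``non-coding``: intergenic, intronic, splice-region and non-coding
  transcript exon variants;
- ``ncRNA``: variants in long non-coding RNAs and microRNAs, tracked as their
  own super-group because ancestral cohorts differ most visibly there (it is
  also counted inside non-coding totals where requested);
- ``regulatory``: transcription-factor binding sites, promoters, enhancers,
  repressors, promoter-flanking regions and open chromatin;
- ``coding``: 5'/3' UTRs, synonymous, missense and nonsense variants.

Between-ancestry category proportions are compared with the plain two-sample
(pooled) two-proportion z-test, two-tailed, flagged at raw p < 0.05; no
continuity correction and no multiplicity adjustment feed the flags, though
Benjamini-Hochberg adjusted p-values are emitted for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VOCABULARY",
    "TERMS_BY_CATEGORY",
    "CATEGORY_GROUP",
    "ProportionTestResult",
    "load_vocabulary",
    "categorize_snps",
    "category_summary",
    "two_proportion_z",
    "compare_category_proportions",
]

# consequence term -> (category, super-group)
VOCABULARY: dict[str, tuple[str, str]] = {
    "intergenic_variant": ("intergenic", "non-coding"),
    "intron_variant": ("intron", "non-coding"),
    "splice_region_variant": ("splice-region", "non-coding"),
    "non_coding_transcript_exon_variant": ("nc-transcript-exon", "non-coding"),
    "lncRNA_variant": ("lncRNA", "ncRNA"),
    "mature_miRNA_variant": ("miRNA", "ncRNA"),
    "TF_binding_site_variant": ("TFBS", "regulatory"),
    "promoter_variant": ("promoter", "regulatory"),
    "enhancer_variant": ("enhancer", "regulatory"),
    "repressor_variant": ("repressor", "regulatory"),
    "promoter_flanking_region_variant": ("promoter-flanking", "regulatory"),
    "open_chromatin_region_variant": ("open-chromatin", "regulatory"),
    "5_prime_UTR_variant": ("5'UTR", "coding"),
    "3_prime_UTR_variant": ("3'UTR", "coding"),
    "synonymous_variant": ("synonymous", "coding"),
    "missense_variant": ("nonsynonymous-missense", "coding"),
    "stop_gained": ("nonsynonymous-nonsense", "coding"),
}

CATEGORY_GROUP: dict[str, str] = {cat: grp for cat, grp in VOCABULARY.values()}

TERMS_BY_CATEGORY: dict[str, list[str]] = {}
for _term, (_cat, _grp) in VOCABULARY.items():
    TERMS_BY_CATEGORY.setdefault(_cat, []).append(_term)


def load_vocabulary(path: str | Path) -> dict[str, tuple[str, str]]:
    """Load a user-edited vocabulary map from YAML (term -> [category, group])."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {term: (v[0], v[1]) for term, v in raw.items()}


def categorize_snps(
    snps: pd.DataFrame, vocabulary: Mapping[str, tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Fill ``category`` and ``group`` from the ``consequence`` column.

    A pure per-row lookup: permuting input rows permutes output rows
    identically. Unknown consequence terms are rejected (no silent 'other').
    """
    vocab = dict(vocabulary) if vocabulary is not None else VOCABULARY
    out = snps.copy()
    unknown = sorted(set(out["consequence"]) - set(vocab))
    if unknown:
        raise ValueError(f"unknown consequence terms (not in vocabulary): {unknown}")
    out["category"] = out["consequence"].map(lambda t: vocab[t][0])
    out["group"] = out["consequence"].map(lambda t: vocab[t][1])
    return out


def category_summary(categorized: pd.DataFrame, by: str = "category") -> pd.DataFrame:
    """Per-ancestry counts per category (or per ``group``), the Fig-1B analogue.

    Shared SNPs appear once per ancestry (long format), so they count in both
    ancestry denominators. Returns one row per (ancestry, label) with the
    count, the ancestry total ``n`` and the proportion.
    """
    counts = categorized.groupby(["ancestry", by], sort=True).size().rename("count").reset_index()
    totals = categorized.groupby("ancestry", sort=True).size().rename("n")
    counts = counts.merge(totals, on="ancestry")
    counts["proportion"] = counts["count"] / counts["n"]
    return counts


@dataclass(frozen=True)
class ProportionTestResult:
    count_a: int
    n_a: int
    count_b: int
    n_b: int
    z: float
    p: float


def two_proportion_z(count_a: int, n_a: int, count_b: int, n_b: int) -> ProportionTestResult:
    """Pooled two-proportion z-test, two-tailed.

    z = (p_a - p_b) / sqrt(phat (1-phat) (1/n_a + 1/n_b)) with
    phat = (count_a + count_b) / (n_a + n_b). Degenerate contract: if the
    pooled proportion is 0 or 1 the statistic is 0 and p = 1.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("n_a and n_b must be >= 1")
    if not (0 <= count_a <= n_a) or not (0 <= count_b <= n_b):
        raise ValueError("counts must lie in [0, n]")
    phat = (count_a + count_b) / (n_a + n_b)
    if phat in (0.0, 1.0):
        return ProportionTestResult(count_a, n_a, count_b, n_b, 0.0, 1.0)
    se = np.sqrt(phat * (1.0 - phat) * (1.0 / n_a + 1.0 / n_b))
    z = (count_a / n_a - count_b / n_b) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return ProportionTestResult(count_a, n_a, count_b, n_b, float(z), float(min(p, 1.0)))


def compare_category_proportions(
    counts_a: Mapping[str, int],
    n_a: int,
    counts_b: Mapping[str, int],
    n_b: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One two-proportion z-test per category between two ancestry summaries.

    Both summaries must cover the same category vocabulary. Flags at raw
    p < ``alpha``; a Benjamini-Hochberg column is added for information only.
    """
    if set(counts_a) != set(counts_b):
        only_a = sorted(set(counts_a) - set(counts_b))
        only_b = sorted(set(counts_b) - set(counts_a))
        raise ValueError(f"mismatched category vocabularies: only_a={only_a}, only_b={only_b}")
    rows = []
    for cat in sorted(counts_a):
        res = two_proportion_z(counts_a[cat], n_a, counts_b[cat], n_b)
        rows.append(
            {
                "category": cat,
                "count_a": res.count_a,
                "n_a": res.n_a,
                "count_b": res.count_b,
                "n_b": res.n_b,
                "prop_a": res.count_a / res.n_a,
                "prop_b": res.count_b / res.n_b,
                "z": res.z,
                "p": res.p,
            }
        )
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < alpha
    out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out
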