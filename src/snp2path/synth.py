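"""Synthetic inputs with planted structure for every pipeline stage.

The generators emulate the shape of an ancestry-stratified Immunochip-style
analysis: two ancestry cohorts of association SNPs with a small shared
fraction (defaults 757 EA / 700 AsA / 20 shared), consequence-category
mixtures mirroring the published distribution (~70% non-coding, ~8% coding,
with the Asian-ancestry cohort carrying roughly twice the ncRNA fraction of
the European one), table-driven eQTL / regulatory / coding lookups with
configurable hit rates, a BIG-C-style 54-category functional scheme and an
I-Scope-style 30-label cell scheme with planted enriched categories, a
STRING-dialect PPI edge list with planted dense modules on a sparse
background, and log2 expression matrices with planted case-shifted
signatures whose latent activity is linearly coupled to clinical metadata
(SLEDAI-like, anti-dsDNA-like, and — negatively — C3-like variables).

The synthetic genome has 22 numbered chromosomes (1-based, fully closed
intervals) and reserves the published chr6 exclusion window so the filter is
exercised; a small fraction of SNPs is deliberately placed inside it. Gene
symbols are deterministic tokens (G000001, ...) so no real symbol can be hit
by accident. Everything is byte-reproducible under a fixed seed.

One deliberate departure from a textbook stochastic block model: background
noise edges are drawn on every node pair EXCEPT pairs joining two distinct
planted modules. Planted modules are ground-truth complexes that downstream
cluster recovery must be able to separate; a seed-relative MCODE cannot
split two equally dense modules joined by a high-weight bridge, so the
generator keeps module-module pairs edge-free (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ConfigError
from . import io as s2p_io
from .enrichment import AnnotationLibrary
from .snp_categories import CATEGORY_GROUP, TERMS_BY_CATEGORY

__all__ = [
    "CHROMOSOME_LENGTH",
    "SynthConfig",
    "PpiSpec",
    "ExprSpec",
    "MetaSpec",
    "LookupTables",
    "AnnotationBundle",
    "PpiNetwork",
    "ExpressionBundle",
    "gen_snp_table",
    "gen_lookup_tables",
    "gen_annotation_library",
    "gen_ppi",
    "gen_expression",
    "write_all",
]

CHROMOSOMES = [str(c) for c in range(1, 23)]
CHROMOSOME_LENGTH = 120_000_000

# Per-ancestry consequence-category proportions (sum to 1): ~70% non-coding,
# 8% coding in both cohorts; AsA ncRNA ~2x EA, EA regulatory > AsA.
_COMMON = {
    "intergenic": 0.32, "intron": 0.30, "splice-region": 0.04, "nc-transcript-exon": 0.04,
    "5'UTR": 0.015, "3'UTR": 0.025, "synonymous": 0.02,
    "nonsynonymous-missense": 0.015, "nonsynonymous-nonsense": 0.005,
}
DEFAULT_CATEGORY_PROPORTIONS: dict[str, dict[str, float]] = {
    "EA": {
        **_COMMON,
        "enhancer": 0.05, "promoter": 0.04, "TFBS": 0.03, "open-chromatin": 0.02,
        "promoter-flanking": 0.015, "repressor": 0.005,
        "lncRNA": 0.04, "miRNA": 0.02,
    },
    "AsA": {
        **_COMMON,
        "enhancer": 0.035, "promoter": 0.025, "TFBS": 0.02, "open-chromatin": 0.015,
        "promoter-flanking": 0.01, "repressor": 0.005,
        "lncRNA": 0.075, "miRNA": 0.035,
    },
}


@dataclass
class PpiSpec:
    n_modules: int = 5
    module_size: int = 12
    p_within: float = 0.8
    p_background: float = 0.05
    n_background_genes: int = 400


@dataclass
class ExprSpec:
    n_genes: int = 1000
    n_case: int = 20
    n_control: int = 20
    set_size: int = 25
    n_decoy_sets: int = 10
    planted: dict[str, float] = field(default_factory=lambda: {"SIG_PLANTED": 1.0})
    noise_sd: float = 1.0
    activity_sd: float = 0.25
    baseline_range: tuple[float, float] = (4.0, 12.0)


@dataclass
class MetaSpec:
    """Linear couplings (intercept, slope on latent activity, noise SD)."""

    signature: str = "SIG_PLANTED"
    coefficients: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "SLEDAI": (6.0, 4.0, 2.0),
            "anti_dsDNA": (50.0, 30.0, 15.0),
            "C3": (100.0, -20.0, 10.0),
        }
    )


@dataclass
class SynthConfig:
    seed: int = 0
    n_snps_per_ancestry: dict[str, int] = field(default_factory=lambda: {"EA": 757, "AsA": 700})
    shared_snp_count: int = 20
    category_proportions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {a: dict(p) for a, p in DEFAULT_CATEGORY_PROPORTIONS.items()}
    )
    hla_snp_fraction: float = 0.02
    eqtl_hit_rate: float = 0.45
    regulatory_hit_rate: float = 0.07
    coding_hit_rate: float = 0.03
    genes_per_hit_mean: dict[str, float] = field(
        default_factory=lambda: {"eqtl": 3.0, "regulatory": 6.0, "coding": 1.0}
    )
    n_genes_universe: int = 5000
    n_functional_categories: int = 54
    n_cell_categories: int = 30
    planted_categories: list[tuple[str, float]] = field(default_factory=lambda: [("FC001", 5.0)])
    signal_set_size: int = 100
    ppi_spec: PpiSpec = field(default_factory=PpiSpec)
    expr_spec: ExprSpec = field(default_factory=ExprSpec)
    meta_spec: MetaSpec = field(default_factory=MetaSpec)

    def universe(self) -> list[str]:
        return [f"G{i:06d}" for i in range(1, self.n_genes_universe + 1)]

    def stage_seed(self, offset: int) -> int:
        return int((self.seed + offset) % (2**31 - 1))


def _validate_snp_config(config: SynthConfig) -> None:
    if config.n_snps_per_ancestry and config.shared_snp_count > min(config.n_snps_per_ancestry.values()):
        raise ConfigError("shared_snp_count exceeds an ancestry's SNP count")
    if not 0 <= config.hla_snp_fraction <= 1:
        raise ConfigError("hla_snp_fraction must be in [0, 1]")
    for anc, props in config.category_proportions.items():
        if any(v < 0 for v in props.values()) or abs(sum(props.values()) - 1.0) > 1e-9:
            raise ConfigError(f"category_proportions for {anc!r} must be non-negative and sum to 1")
        unknown = sorted(set(props) - set(CATEGORY_GROUP))
        if unknown:
            raise ConfigError(f"unknown categories in proportions for {anc!r}: {unknown}")


def _sample_consequence(rng: np.random.Generator, props: dict[str, float]) -> str:
    cats = sorted(props)
    weights = np.array([props[c] for c in cats], dtype=float)
    cat = cats[rng.choice(len(cats), p=weights / weights.sum())]
    terms = sorted(TERMS_BY_CATEGORY[cat])
    return terms[rng.integers(len(terms))]


def gen_snp_table(config: SynthConfig) -> pd.DataFrame:
    """Long-format SNP table: one row per SNP x ancestry label.

    Shared SNPs are duplicated per ancestry with both labels recorded in the
    ``ancestries`` column; per-ancestry row counts (shared included) and the
    shared count match the config exactly.
    """
    _validate_snp_config(config)
    rng = np.random.default_rng(config.stage_seed(0))
    from .gene_mapping import HLA_WINDOW

    ancestries = sorted(config.n_snps_per_ancestry)
    shared = config.shared_snp_count if len(ancestries) >= 2 else 0
    plan: list[tuple[list[str]]] = []
    plan.extend([tuple(ancestries)] * shared)
    for anc in ancestries:
        plan.extend([(anc,)] * (config.n_snps_per_ancestry[anc] - shared))

    rows = []
    for i, labels in enumerate(plan, start=1):
        snp_id = f"rs{i:07d}"
        if rng.random() < config.hla_snp_fraction:
            chrom = HLA_WINDOW[0]
            pos = int(rng.integers(HLA_WINDOW[1], HLA_WINDOW[2] + 1))
        else:
            chrom = CHROMOSOMES[rng.integers(len(CHROMOSOMES))]
            pos = int(rng.integers(1, CHROMOSOME_LENGTH + 1))
        props_list = [config.category_proportions[a] for a in labels]
        props = {c: float(np.mean([p.get(c, 0.0) for p in props_list])) for c in props_list[0]}
        consequence = _sample_consequence(rng, props)
        assoc_p = float(10 ** -rng.uniform(3, 8))
        joined = ",".join(labels)
        for anc in labels:
            rows.append((snp_id, chrom, pos, anc, joined, assoc_p, consequence))
    return pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "ancestry", "ancestries", "assoc_p", "consequence"]
    )


@dataclass
class LookupTables:
    eqtl: pd.DataFrame
    regulatory: pd.DataFrame
    coding: pd.DataFrame
    coords: pd.DataFrame
    universe: list[str]
    p_eligible: list[str]  # ground truth: SNPs given no lookup hit anywhere


def gene_coordinates(universe: list[str]) -> pd.DataFrame:
    """Deterministic non-overlapping 20 kb gene intervals, round-robin per chromosome."""
    rows = []
    per_chrom: dict[str, int] = {c: 0 for c in CHROMOSOMES}
    for i, gene in enumerate(universe):
        chrom = CHROMOSOMES[i % len(CHROMOSOMES)]
        k = per_chrom[chrom]
        start = 1_000_000 + k * 100_000
        rows.append((chrom, start, start + 19_999, gene))
        per_chrom[chrom] = k + 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def gen_lookup_tables(config: SynthConfig, snps: pd.DataFrame) -> LookupTables:
    """eQTL / regulatory / coding SNP-to-gene tables plus gene coordinates."""
    for name in ("eqtl_hit_rate", "regulatory_hit_rate", "coding_hit_rate"):
        rate = getattr(config, name)
        if not 0 <= rate <= 1:
            raise ConfigError(f"{name} must be in [0, 1], got {rate}")
    rng = np.random.default_rng(config.stage_seed(1))
    universe = config.universe()
    coords = gene_coordinates(universe)
    snp_ids = snps.drop_duplicates("snp_id")["snp_id"].tolist()
    tables: dict[str, pd.DataFrame] = {}
    hit_anywhere: set[str] = set()
    for source, rate in (
        ("eqtl", config.eqtl_hit_rate),
        ("regulatory", config.regulatory_hit_rate),
        ("coding", config.coding_hit_rate),
    ):
        mean = config.genes_per_hit_mean[source]
        if mean < 1:
            raise ConfigError(f"genes_per_hit_mean[{source!r}] must be >= 1")
        rows = []
        for snp_id in snp_ids:
            if rng.random() >= rate:
                continue
            hit_anywhere.add(snp_id)
            n_genes = 1 + int(rng.poisson(mean - 1.0))
            for gene in rng.choice(universe, size=min(n_genes, len(universe)), replace=False):
                rows.append((snp_id, gene, source))
        tables[source] = pd.DataFrame(rows, columns=["snp_id", "gene", "source"])
    p_eligible = [s for s in snp_ids if s not in hit_anywhere]
    return LookupTables(
        eqtl=tables["eqtl"], regulatory=tables["regulatory"], coding=tables["coding"],
        coords=coords, universe=universe, p_eligible=p_eligible,
    )


@dataclass
class AnnotationBundle:
    functional: AnnotationLibrary
    cell: AnnotationLibrary
    signal_sets: dict[str, list[str]]


def gen_annotation_library(config: SynthConfig) -> AnnotationBundle:
    """Functional (exclusive) and cell-type (overlapping) schemes plus signal sets.

    Every universe gene gets exactly one functional category; roughly 40% of
    genes carry one or two cell labels. For each planted (category, odds)
    pair a 'signal' gene set is drawn with in-category genes ``odds`` times
    likelier, the ground truth for downstream enrichment recovery.
    """
    if config.n_functional_categories < 1 or config.n_cell_categories < 1:
        raise ConfigError("need at least one functional and one cell category")
    rng = np.random.default_rng(config.stage_seed(2))
    universe = config.universe()
    fcats = [f"FC{i:03d}" for i in range(1, config.n_functional_categories + 1)]
    ccats = [f"CC{i:03d}" for i in range(1, config.n_cell_categories + 1)]
    assignment = rng.integers(len(fcats), size=len(universe))
    func_rows = [(g, fcats[assignment[i]]) for i, g in enumerate(universe)]
    cell_rows = []
    for g in universe:
        if rng.random() < 0.4:
            for c in rng.choice(ccats, size=int(rng.integers(1, 3)), replace=False):
                cell_rows.append((g, c))
    functional = AnnotationLibrary.from_table(
        pd.DataFrame(func_rows, columns=["gene", "category"]),
        scheme="functional-synth", exclusive=True, universe=set(universe),
    )
    cell = AnnotationLibrary.from_table(
        pd.DataFrame(cell_rows, columns=["gene", "category"]),
        scheme="cell-synth", exclusive=False, universe=set(universe),
    )
    signal_sets: dict[str, list[str]] = {}
    for cat, odds in config.planted_categories:
        if odds <= 0:
            raise ConfigError(f"planted enrichment odds must be positive, got {odds}")
        in_cat = np.array([cat in functional.memberships.get(g, ()) for g in universe])
        w = np.where(in_cat, odds, 1.0)
        size = min(config.signal_set_size, len(universe))
        picked = rng.choice(universe, size=size, replace=False, p=w / w.sum())
        signal_sets[f"SIG_{cat}"] = sorted(picked.tolist())
    return AnnotationBundle(functional=functional, cell=cell, signal_sets=signal_sets)


@dataclass
class PpiNetwork:
    edges: pd.DataFrame
    modules: dict[str, list[str]]
    nodes: list[str]


def gen_ppi(config: SynthConfig, candidate_genes: list[str] | None = None) -> PpiNetwork:
    """STRING-dialect edge list with node-disjoint planted dense modules.

    Module members are drawn from ``candidate_genes`` when given (e.g. the
    genes the lookup tables actually linked, so the planted complexes sit
    inside the SNP-predicted cohort), otherwise from the universe. Background
    noise edges cover every pair except module-module pairs (module
    separability is part of the planted ground truth; see module docstring).
    Planted edges carry high confidence scores (700-999), noise edges 150-999.
    """
    spec = config.ppi_spec
    if not 0 <= spec.p_background <= 1 or not 0 <= spec.p_within <= 1:
        raise ConfigError("edge probabilities must be in [0, 1]")
    if spec.n_modules > 0 and spec.p_within <= spec.p_background:
        raise ConfigError("p_within must exceed p_background")
    n_module_genes = spec.n_modules * spec.module_size
    if n_module_genes > min(spec.n_background_genes, config.n_genes_universe):
        raise ConfigError("modules do not fit: n_modules * module_size exceeds the node budget")
    rng = np.random.default_rng(config.stage_seed(3))
    universe = config.universe()
    pool = sorted(set(candidate_genes)) if candidate_genes else universe
    if n_module_genes > len(pool):
        raise ConfigError("modules do not fit inside the candidate gene pool")
    module_genes = sorted(rng.choice(pool, size=n_module_genes, replace=False).tolist())
    rng.shuffle(module_genes)
    modules = {
        f"M{i + 1:02d}": sorted(module_genes[i * spec.module_size : (i + 1) * spec.module_size])
        for i in range(spec.n_modules)
    }
    rest_pool = sorted(set(universe) - set(module_genes))
    n_rest = spec.n_background_genes - n_module_genes
    background_nodes = sorted(rng.choice(rest_pool, size=n_rest, replace=False).tolist()) if n_rest else []
    nodes = sorted(module_genes + background_nodes)
    node_module = {g: mid for mid, genes in modules.items() for g in genes}

    rows = []
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            u, v = nodes[a], nodes[b]
            mu, mv = node_module.get(u), node_module.get(v)
            if mu is not None and mu == mv:
                if rng.random() < spec.p_within:
                    rows.append((u, v, int(rng.integers(700, 1000))))
            elif mu is not None and mv is not None:
                continue  # no noise edges between two distinct planted modules
            else:
                if rng.random() < spec.p_background:
                    rows.append((u, v, int(rng.integers(150, 1000))))
    edges = pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])
    return PpiNetwork(edges=edges, modules=modules, nodes=nodes)


@dataclass
class ExpressionBundle:
    expr: pd.DataFrame  # genes x samples, log2 scale
    metadata: pd.DataFrame  # per sample: group, SLEDAI, anti_dsDNA, C3, ancestry
    sets: dict[str, list[str]]  # planted + decoy signatures
    activity: pd.DataFrame  # ground-truth latent activity per planted set


def gen_expression(config: SynthConfig) -> ExpressionBundle:
    """Log2 expression with planted case-shifted signatures and coupled metadata.

    Controls are baseline + Gaussian noise; cases additionally shift each
    planted set's genes by that set's latent activity delta + N(0, activity
    jitter), shared coherently across the set's genes within a sample.
    Metadata variables are linear in the chosen signature's latent activity.
    Decoy sets are drawn from non-planted genes and carry no shift.
    """
    spec = config.expr_spec
    if spec.n_case < 2 or spec.n_control < 2:
        raise ConfigError("need at least 2 case and 2 control samples")
    if spec.n_genes > config.n_genes_universe:
        raise ConfigError("expr n_genes exceeds the gene universe")
    rng = np.random.default_rng(config.stage_seed(4))
    universe = config.universe()
    genes = sorted(rng.choice(universe, size=spec.n_genes, replace=False).tolist())
    samples = [f"CTRL{i:03d}" for i in range(1, spec.n_control + 1)] + [
        f"SLE{i:03d}" for i in range(1, spec.n_case + 1)
    ]
    case_mask = np.array([s.startswith("SLE") for s in samples])

    free = list(genes)
    sets: dict[str, list[str]] = {}
    for name in sorted(spec.planted):
        picked = sorted(rng.choice(free, size=spec.set_size, replace=False).tolist())
        sets[name] = picked
        free = [g for g in free if g not in set(picked)]
    for d in range(1, spec.n_decoy_sets + 1):
        sets[f"SIG_DECOY{d:02d}"] = sorted(rng.choice(free, size=spec.set_size, replace=False).tolist())

    lo, hi = spec.baseline_range
    baseline = rng.uniform(lo, hi, size=len(genes))
    X = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(len(genes), len(samples)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    activity: dict[str, np.ndarray] = {}
    for name in sorted(spec.planted):
        delta = spec.planted[name]
        a = delta * case_mask.astype(float) + rng.normal(0.0, spec.activity_sd, size=len(samples))
        activity[name] = a
        rows = [gene_pos[g] for g in sets[name]]
        X[rows, :] += a[None, :]

    sig = config.meta_spec.signature
    if sig not in activity:
        raise ConfigError(f"meta_spec.signature {sig!r} is not a planted set")
    meta_rows: dict[str, np.ndarray] = {}
    for var, (b0, b1, sd) in sorted(config.meta_spec.coefficients.items()):
        meta_rows[var] = b0 + b1 * activity[sig] + rng.normal(0.0, sd, size=len(samples))
    metadata = pd.DataFrame(
        {
            "group": np.where(case_mask, "SLE", "control"),
            **{k: np.round(v, 4) for k, v in meta_rows.items()},
            "ancestry": rng.choice(["EA", "AsA"], size=len(samples)),
        },
        index=pd.Index(samples, name="sample"),
    )
    if "SLEDAI" in metadata:
        metadata["SLEDAI"] = metadata["SLEDAI"].clip(lower=0.0)
    expr = pd.DataFrame(np.round(X, 6), index=pd.Index(genes, name="gene"), columns=samples)
    act = pd.DataFrame(activity, index=pd.Index(samples, name="sample"))
    return ExpressionBundle(expr=expr, metadata=metadata, sets=sets, activity=act)


def write_all(config: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate everything and write the full set of pipeline input files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    snps = gen_snp_table(config)
    lookups = gen_lookup_tables(config, snps)
    ann = gen_annotation_library(config)
    linked = sorted(
        set(lookups.eqtl["gene"]) | set(lookups.regulatory["gene"]) | set(lookups.coding["gene"])
    )
    ppi = gen_ppi(config, candidate_genes=linked or None)
    bundle = gen_expression(config)

    paths: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame, index: bool = False) -> None:
        paths[name] = out / f"{name}.tsv"
        s2p_io.write_tsv(df, paths[name], header_comment=f"synthetic {name}; seed={config.seed}", index=index)

    _write("snps", snps)
    _write("eqtl", lookups.eqtl)
    _write("regulatory", lookups.regulatory)
    _write("coding", lookups.coding)
    _write("gene_coords", lookups.coords)
    func_rows = [(g, sorted(c)[0], "functional") for g, c in sorted(ann.functional.memberships.items())]
    cell_rows = [(g, c, "cell") for g, cs in sorted(ann.cell.memberships.items()) for c in sorted(cs)]
    _write("functional_annotation", pd.DataFrame(func_rows, columns=["gene", "category", "scheme"]))
    _write("cell_annotation", pd.DataFrame(cell_rows, columns=["gene", "category", "scheme"]))
    _write("ppi_edges", ppi.edges)
    _write("expression", bundle.expr, index=True)
    _write("metadata", bundle.metadata, index=True)
    paths["signatures"] = out / "signatures.gmt"
    s2p_io.write_gmt(bundle.sets, paths["signatures"])
    paths["signal_sets"] = out / "signal_sets.gmt"
    s2p_io.write_gmt(ann.signal_sets, paths["signal_sets"])
    return paths
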