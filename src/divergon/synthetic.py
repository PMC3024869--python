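"""Synthetic inputs with the statistical structure the pipeline assumes.

Real analyses of divergent gene pairs draw on curated genome
annotations, large expression compendia, TF-target databases and GO
annotations.  This module generates stand-ins for all of them with known
ground truth, so every pipeline stage can be exercised and validated:

* a focal genome with planted head-to-head pairs whose TSS distances
  follow a configurable interval mixture, plus partner-species
  annotations and ortholog maps realising a nested conservation chain
  (conservation probability may depend on promoter length, making short
  pairs more conserved);
* expression datasets drawn from a factor model: each planted pair loads
  on a pair-specific factor (within-pair correlation ``rho_pair``, which
  may increase with conservation level), all pair genes share a weak
  common factor (``rho_inter``), and background genes are independent;
* a TF->target map in which planted pairs share at least one TF with a
  per-level probability, plus occasional pairs where one gene is itself
  a TF regulating its partner;
* a small three-subsystem ontology (rooted trees with a few shortcut
  is_a edges) with planted co-annotation of pair genes.

Everything is driven by a single integer seed; identical configurations
produce identical data.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .coexpression import ExpressionDataset
from .conservation import OrthologMap, level_labels
from .gene_models import GeneRecord, H2HPair, PairSet
from .go_semantics import SUBSYSTEMS, AnnotationSet, GoDag
from .tf_regulation import TFMap

__all__ = [
    "SimulationConfig",
    "SimulatedData",
    "simulate_genome",
    "simulate_expression",
    "simulate_tf_map",
    "simulate_ontology",
    "simulate_all",
    "write_simulation",
]

_NAMESPACE_OF = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the package's study conditions.

    Distance mixture weights echo the observed predominance of sub-400 bp
    bidirectional promoters; conservation steps are Bernoulli chains whose
    success probability is higher for short (<= ``short_distance``)
    promoters, so nesting is structural and short pairs are enriched at
    deeper levels.  Planted effect sizes (``rho_pair``, ``p_share``,
    ``p_coannotate``) increase with conservation depth.
    """

    seed: int
    # genome
    n_chromosomes: int = 5
    genes_per_chromosome: int = 600
    n_h2h_pairs: int = 500
    tss_distance_mixture: tuple = (
        ((-200, 0), 0.08),
        ((0, 100), 0.14),
        ((100, 200), 0.20),
        ((200, 400), 0.21),
        ((400, 1000), 0.37),
    )
    gene_length: tuple[int, int] = (2000, 10000)
    intergenic_gap: tuple[int, int] = (2000, 20000)
    species: tuple[str, ...] = ("mouse", "chicken", "fugu")
    # conservation chain: per species step, (p if short promoter, p otherwise)
    conservation_probs: tuple = ((0.55, 0.30), (0.60, 0.40), (0.50, 0.30))
    short_distance: int = 100
    p_ortholog_background: float = 0.7
    # expression
    n_datasets: int = 4
    samples_per_dataset: int = 100
    rho_pair: tuple[float, ...] = (0.45, 0.55, 0.60, 0.65)  # by level depth
    rho_inter: float = 0.2
    rho_background: float = 0.0
    # TF map
    tf_pool_size: int = 200
    tfs_per_gene: int = 3
    p_tf_associated: float = 0.8
    p_share: tuple[float, ...] = (0.25, 0.50, 0.70, 0.85)  # by level depth
    p_multi_share: float = 0.35  # given sharing, share two TFs instead of one
    p_self_regulate: float = 0.02
    # ontology
    dag_depth: int = 4
    branching: int = 3
    n_shortcuts: int = 3
    terms_per_gene: int = 2
    p_annotated: float = 0.85
    p_coannotate: tuple[float, ...] = (0.30, 0.50, 0.65, 0.80)  # by level depth

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        weights = [w for _, w in self.tss_distance_mixture]
        if any(w < 0 for w in weights) or not np.isclose(sum(weights), 1.0):
            raise ValueError("tss_distance_mixture weights must be >= 0 and sum to 1")
        n_levels = len(self.species) + 1
        for name in ("rho_pair", "p_share", "p_coannotate"):
            if len(getattr(self, name)) != n_levels:
                raise ValueError(f"{name} needs one value per conservation level")
        if len(self.conservation_probs) != len(self.species):
            raise ValueError("conservation_probs needs one entry per species")
        for probs in (self.p_share + self.p_coannotate
                      + tuple(p for pair in self.conservation_probs for p in pair)
                      + (self.p_tf_associated, self.p_annotated,
                         self.p_self_regulate, self.p_multi_share,
                         self.p_ortholog_background)):
            if not 0.0 <= probs <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.rho_background <= self.rho_inter <= min(self.rho_pair):
            raise ValueError(
                "need 0 <= rho_background <= rho_inter <= rho_pair "
                "(factor-model correlation structure must be PSD)"
            )
        if max(self.rho_pair) >= 1.0:
            raise ValueError("rho_pair must be < 1")
        if self.tf_pool_size < self.tfs_per_gene:
            raise ValueError("tf_pool_size must be >= tfs_per_gene")
        if self.dag_depth < 2:
            raise ValueError("dag_depth must be >= 2")
        if min(self.intergenic_gap) <= 1000:
            raise ValueError("intergenic gaps must exceed 1 kb to keep filler "
                             "genes out of detection range")
        if self.genes_per_chromosome * self.n_chromosomes < 2 * self.n_h2h_pairs:
            raise ValueError("not enough genes to host the requested pairs")

    @property
    def levels(self) -> list[str]:
        return level_labels(self.species)


@dataclass
class SimulatedData:
    """Bundle of generated inputs plus the ground-truth table."""

    config: SimulationConfig
    genes: list[GeneRecord]
    truth: pd.DataFrame  # minus_gene, plus_gene, chrom, tss_distance, depth, level
    species_genes: dict[str, list[GeneRecord]]
    ortholog_maps: dict[str, OrthologMap]
    datasets: list[ExpressionDataset]
    tfmap: TFMap
    dag: GoDag
    annotations: AnnotationSet

    @property
    def truth_pairs(self) -> PairSet:
        return PairSet.from_h2h(
            [
                H2HPair(r.minus_gene, r.plus_gene, r.chrom, int(r.tss_distance))
                for r in self.truth.itertuples(index=False)
            ],
            label="truth",
        )


def _draw_distance(rng: np.random.Generator, mixture) -> int:
    weights = np.array([w for _, w in mixture])
    k = rng.choice(len(mixture), p=weights / weights.sum())
    lo, hi = mixture[k][0]
    return int(rng.integers(lo + 1, hi + 1))  # (lo, hi], integers


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneRecord], pd.DataFrame, dict[str, list[GeneRecord]], dict[str, OrthologMap]]:
    """Plant h2h pairs in a focal genome and echo them into partner species.

    Returns the focal annotation, the truth table (one row per planted
    pair with its TSS distance and conservation depth), the partner
    species annotations (conserved pairs arranged head-to-head there) and
    the ortholog maps.  Filler genes are spaced by more than the maximal
    promoter length so the planted pairs are exactly the detectable ones.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    per_chrom = np.full(config.n_chromosomes, config.n_h2h_pairs // config.n_chromosomes)
    per_chrom[: config.n_h2h_pairs % config.n_chromosomes] += 1

    genes: list[GeneRecord] = []
    truth_rows = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"g{counter:05d}"

    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        n_pairs = int(per_chrom[ci])
        n_fillers = config.genes_per_chromosome - 2 * n_pairs
        if n_fillers < 0:
            raise ValueError("infeasible packing: too many pairs per chromosome")
        items = ["pair"] * n_pairs + ["filler"] * n_fillers
        rng.shuffle(items)
        pos = int(rng.integers(10_000, 50_000))
        for item in items:
            glen = int(rng.integers(*config.gene_length))
            if item == "filler":
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "+":
                    rec = GeneRecord(new_id(), chrom, "+", tss=pos, tes=pos + glen)
                else:
                    rec = GeneRecord(new_id(), chrom, "-", tss=pos + glen, tes=pos)
                genes.append(rec)
                pos = pos + glen + int(rng.integers(*config.intergenic_gap))
            else:
                d = _draw_distance(rng, config.tss_distance_mixture)
                glen2 = int(rng.integers(*config.gene_length))
                m_tss = pos + glen  # minus gene transcribes leftward
                minus = GeneRecord(new_id(), chrom, "-", tss=m_tss, tes=pos)
                p_tss = m_tss + d
                plus = GeneRecord(new_id(), chrom, "+", tss=p_tss, tes=p_tss + glen2)
                genes.append(minus)
                genes.append(plus)
                depth = 0
                short = d <= config.short_distance
                for p_short, p_long in config.conservation_probs:
                    if rng.random() < (p_short if short else p_long):
                        depth += 1
                    else:
                        break
                truth_rows.append(
                    {
                        "minus_gene": minus.gene_id,
                        "plus_gene": plus.gene_id,
                        "chrom": chrom,
                        "tss_distance": d,
                        "depth": depth,
                        "level": config.levels[depth],
                    }
                )
                pos = max(m_tss, p_tss + glen2) + int(rng.integers(*config.intergenic_gap))

    truth = pd.DataFrame(truth_rows)

    # partner species: conserved pairs stay head-to-head, everything else is
    # a lone + strand gene; ortholog names get the species initial suffix.
    species_genes: dict[str, list[GeneRecord]] = {}
    ortholog_maps: dict[str, OrthologMap] = {}
    pair_gene_depth = {}
    for r in truth.itertuples(index=False):
        pair_gene_depth[r.minus_gene] = r.depth
        pair_gene_depth[r.plus_gene] = r.depth
    for si, sp in enumerate(config.species):
        suffix = sp[0].lower()
        sp_genes: list[GeneRecord] = []
        mapping: dict[str, str] = {}
        pos = 10_000
        chrom = f"{suffix}chr1"
        for r in truth.itertuples(index=False):
            if r.depth >= si + 1:
                d = int(r.tss_distance)
                glen1 = int(rng.integers(*config.gene_length))
                glen2 = int(rng.integers(*config.gene_length))
                m_id = f"{r.minus_gene}_{suffix}"
                p_id = f"{r.plus_gene}_{suffix}"
                m_tss = pos + glen1
                sp_genes.append(GeneRecord(m_id, chrom, "-", tss=m_tss, tes=pos))
                sp_genes.append(
                    GeneRecord(p_id, chrom, "+", tss=m_tss + d, tes=m_tss + d + glen2)
                )
                mapping[r.minus_gene] = m_id
                mapping[r.plus_gene] = p_id
                pos = max(m_tss, m_tss + d + glen2) + int(
                    rng.integers(*config.intergenic_gap)
                )
        for g in genes:
            if g.gene_id in mapping:
                continue
            if rng.random() < config.p_ortholog_background:
                gid = f"{g.gene_id}_{suffix}"
                glen = int(rng.integers(*config.gene_length))
                sp_genes.append(GeneRecord(gid, chrom, "+", tss=pos, tes=pos + glen))
                mapping[g.gene_id] = gid
                pos = pos + glen + int(rng.integers(*config.intergenic_gap))
        species_genes[sp] = sp_genes
        ortholog_maps[sp] = OrthologMap(species=sp, mapping=mapping)
    return genes, truth, species_genes, ortholog_maps


def simulate_expression(
    config: SimulationConfig,
    truth: pd.DataFrame,
    genes: Sequence[GeneRecord],
    rng: np.random.Generator | None = None,
) -> list[ExpressionDataset]:
    """Factor-model expression: planted pairs correlate, background doesn't.

    Each gene's profile is ``a0*f_global + a1*f_h2h + b*f_pair + c*eps``
    with loadings chosen so pair genes correlate at ``rho_pair[depth]``,
    any two pair genes at ``rho_inter``, and everything else at
    ``rho_background``.  Datasets are sampled independently; marginals
    are standard normal (the downstream statistics are correlation and
    rank based, hence marginal-free).
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    gene_ids = [g.gene_id for g in genes]
    n_genes = len(gene_ids)
    pair_index = np.full(n_genes, -1)
    depth_of = np.zeros(n_genes, dtype=int)
    loc = {g: i for i, g in enumerate(gene_ids)}
    for k, r in enumerate(truth.itertuples(index=False)):
        for gid in (r.minus_gene, r.plus_gene):
            pair_index[loc[gid]] = k
            depth_of[loc[gid]] = r.depth
    is_pair_gene = pair_index >= 0

    a0 = np.sqrt(config.rho_background)
    a1 = np.sqrt(config.rho_inter - config.rho_background)
    rho_pair = np.asarray(config.rho_pair)
    b_gene = np.where(
        is_pair_gene, np.sqrt(rho_pair[depth_of] - config.rho_inter), 0.0
    )
    a1_gene = np.where(is_pair_gene, a1, 0.0)
    c_gene = np.sqrt(1.0 - a0**2 - a1_gene**2 - b_gene**2)

    n_pairs = len(truth)
    datasets = []
    for di in range(config.n_datasets):
        n = config.samples_per_dataset
        f_global = rng.standard_normal(n)
        f_h2h = rng.standard_normal(n)
        f_pair = rng.standard_normal((n_pairs, n))
        eps = rng.standard_normal((n_genes, n))
        X = a0 * f_global + a1_gene[:, None] * f_h2h + c_gene[:, None] * eps
        has_pair = pair_index >= 0
        X[has_pair] += b_gene[has_pair, None] * f_pair[pair_index[has_pair]]
        df = pd.DataFrame(
            X, index=pd.Index(gene_ids, name="gene_id"),
            columns=[f"s{j:03d}" for j in range(n)],
        )
        datasets.append(ExpressionDataset(dataset_id=f"ds{di + 1}", values=df))
    return datasets


def simulate_tf_map(
    config: SimulationConfig,
    truth: pd.DataFrame,
    genes: Sequence[GeneRecord],
    rng: np.random.Generator | None = None,
) -> TFMap:
    """Bipartite TF->target map with planted per-level sharing.

    Each gene is TF-associated with probability ``p_tf_associated`` and
    then draws ``tfs_per_gene`` distinct TFs from the pool; a planted
    pair whose genes are both associated shares at least one TF with
    probability ``p_share[depth]``.  With probability ``p_self_regulate``
    one pair gene is additionally recorded as a TF of its partner.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    pool = [f"TF{i:04d}" for i in range(config.tf_pool_size)]
    targets: dict[str, set[str]] = {}
    for g in genes:
        if rng.random() < config.p_tf_associated:
            tfs = rng.choice(config.tf_pool_size, size=config.tfs_per_gene, replace=False)
            targets[g.gene_id] = {pool[i] for i in tfs}
    p_share = np.asarray(config.p_share)
    for r in truth.itertuples(index=False):
        a, b = r.minus_gene, r.plus_gene
        if a in targets and b in targets:
            if rng.random() < p_share[r.depth]:
                # share one TF, or two with probability p_multi_share
                n_common = 1
                if config.tfs_per_gene >= 2 and rng.random() < config.p_multi_share:
                    n_common = 2
                donors = [
                    sorted(targets[a])[i]
                    for i in rng.choice(len(targets[a]), size=n_common, replace=False)
                ]
                victims = [
                    sorted(targets[b])[i]
                    for i in rng.choice(len(targets[b]), size=n_common, replace=False)
                ]
                for donor, victim in zip(donors, victims):
                    if donor not in targets[b]:
                        targets[b].discard(victim)
                        targets[b].add(donor)
        if rng.random() < config.p_self_regulate:
            targets.setdefault(b, set()).add(a)
    return TFMap(targets={g: frozenset(t) for g, t in targets.items()})


def simulate_ontology(
    config: SimulationConfig,
    truth: pd.DataFrame,
    genes: Sequence[GeneRecord],
    rng: np.random.Generator | None = None,
) -> tuple[GoDag, AnnotationSet]:
    """Three-subsystem toy ontology with planted pair co-annotation.

    Each subsystem is a rooted ``branching``-ary tree of ``dag_depth``
    levels plus a few shortcut is_a edges to shallower ancestors (the
    levelled construction keeps it acyclic and single rooted).  Genes are
    annotated to random non-root terms; a planted pair is co-annotated to
    one shared term in a random subsystem with probability
    ``p_coannotate[depth]``.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    parents: dict[str, frozenset[str]] = {}
    subsystem: dict[str, str] = {}
    terms_by_ss: dict[str, list[str]] = {}
    for ss in SUBSYSTEMS:
        levels: list[list[str]] = []
        tid = 0
        for depth in range(config.dag_depth):
            width = 1 if depth == 0 else len(levels[-1]) * config.branching
            level_terms = []
            for _ in range(width):
                term = f"T:{ss}{tid:04d}"
                tid += 1
                if depth == 0:
                    parents[term] = frozenset()
                else:
                    parent = levels[-1][len(level_terms) // config.branching]
                    parents[term] = frozenset({parent})
                subsystem[term] = ss
                level_terms.append(term)
            levels.append(level_terms)
        # shortcut edges: deep term -> extra ancestor on a shallower level
        flat = [t for lv in levels for t in lv]
        n_shortcuts = config.n_shortcuts if config.dag_depth >= 3 else 0
        for _ in range(n_shortcuts):
            deep_level = int(rng.integers(2, config.dag_depth))
            child = levels[deep_level][int(rng.integers(len(levels[deep_level])))]
            up_level = int(rng.integers(0, deep_level - 1))
            extra = levels[up_level][int(rng.integers(len(levels[up_level])))]
            parents[child] = parents[child] | {extra}
        terms_by_ss[ss] = [t for t in flat if parents[t]]  # non-root terms
    dag = GoDag(parents=parents, subsystem=subsystem)

    by_ss: dict[str, dict[str, set[str]]] = {ss: {} for ss in SUBSYSTEMS}
    for g in genes:
        for ss in SUBSYSTEMS:
            if rng.random() < config.p_annotated:
                pool = terms_by_ss[ss]
                picks = rng.choice(len(pool), size=config.terms_per_gene, replace=False)
                by_ss[ss][g.gene_id] = {pool[i] for i in picks}
    p_co = np.asarray(config.p_coannotate)
    for r in truth.itertuples(index=False):
        if rng.random() < p_co[r.depth]:
            ss = SUBSYSTEMS[int(rng.integers(len(SUBSYSTEMS)))]
            pool = terms_by_ss[ss]
            shared = pool[int(rng.integers(len(pool)))]
            for gid in (r.minus_gene, r.plus_gene):
                by_ss[ss].setdefault(gid, set()).add(shared)
    annotations = AnnotationSet(
        by_subsystem={
            ss: {g: frozenset(ts) for g, ts in genes_.items()}
            for ss, genes_ in by_ss.items()
        }
    )
    return dag, annotations


def simulate_all(config: SimulationConfig) -> SimulatedData:
    """Run every generator stage off one seed."""
    genes, truth, species_genes, ortholog_maps = simulate_genome(config)
    datasets = simulate_expression(config, truth, genes)
    tfmap = simulate_tf_map(config, truth, genes)
    dag, annotations = simulate_ontology(config, truth, genes)
    return SimulatedData(
        config=config,
        genes=genes,
        truth=truth,
        species_genes=species_genes,
        ortholog_maps=ortholog_maps,
        datasets=datasets,
        tfmap=tfmap,
        dag=dag,
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def _write_annotation_tsv(genes: Sequence[GeneRecord], path: str) -> None:
    pd.DataFrame(
        [
            {"gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
             "tss": g.tss, "tes": g.tes}
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def _write_obo(dag: GoDag, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for term in sorted(dag.parents):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {term}\n")
            fh.write(f"namespace: {_NAMESPACE_OF[dag.subsystem[term]]}\n")
            for p in sorted(dag.parents[term]):
                fh.write(f"is_a: {p} ! {p}\n")


def write_simulation(data: SimulatedData, outdir: str) -> dict[str, str]:
    """Write every generated input as plain-text files; returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    paths["annotation"] = os.path.join(outdir, "annotation.tsv")
    _write_annotation_tsv(data.genes, paths["annotation"])
    for sp, sp_genes in data.species_genes.items():
        key = f"annotation_{sp}"
        paths[key] = os.path.join(outdir, f"annotation_{sp}.tsv")
        _write_annotation_tsv(sp_genes, paths[key])
        okey = f"orthologs_{sp}"
        paths[okey] = os.path.join(outdir, f"orthologs_{sp}.tsv")
        pd.DataFrame(
            sorted(data.ortholog_maps[sp].mapping.items())
        ).to_csv(paths[okey], sep="\t", header=False, index=False)

    manifest = []
    for ds in data.datasets:
        p = os.path.join(outdir, f"expr_{ds.dataset_id}.tsv")
        ds.to_tsv(p)
        # basenames keep the bundle relocatable; readers resolve relative
        # to the manifest's own directory
        manifest.append({"dataset_id": ds.dataset_id, "path": os.path.basename(p)})
    paths["manifest"] = os.path.join(outdir, "datasets.tsv")
    pd.DataFrame(manifest).to_csv(paths["manifest"], sep="\t", index=False)

    paths["tf"] = os.path.join(outdir, "tf.tsv")
    data.tfmap.to_table(paths["tf"])
    paths["obo"] = os.path.join(outdir, "ontology.obo")
    _write_obo(data.dag, paths["obo"])
    paths["annot"] = os.path.join(outdir, "annotations.tsv")
    data.annotations.to_table(paths["annot"])
    paths["truth"] = os.path.join(outdir, "truth.tsv")
    data.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["config"] = os.path.join(outdir, "sim_config.json")
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(data.config), fh, indent=2, default=list)
    return paths
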