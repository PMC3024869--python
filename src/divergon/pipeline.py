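"""Orchestration of the full conservation-stratified pair analysis.

The pipeline runs detection -> conservation stratification ->
coexpression -> TF sharing -> functional similarity, builds random and
same-strand-adjacent control sets, and applies a two-stage decision rule
to each candidate feature of the head-to-head arrangement:

1. the feature must differ significantly from its control set, and
2. it must move consistently (monotonically) across the nested
   conservation levels.

A feature passing both stages is declared ``inherent``; one failing
stage 1, or moving opposite to the claimed direction, is ``negated``;
anything else (significant vs control but inconsistent across levels) is
``postponed``.  All tables, test results and verdicts are collected in a
:class:`StratifiedReport` and optionally written to an output directory
as TSV tables plus a JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import conservation as cons
from . import coexpression as coex
from . import gene_models as gm
from . import go_semantics as gos
from . import tf_regulation as tfr

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StratifiedReport", "compare_groups", "run_pipeline"]

VERDICTS = ("inherent", "negated", "postponed")


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float], test: str = "welch_t"
) -> tuple[float, float]:
    """Two-group comparison: Welch t-test or Wilcoxon rank-sum.

    The rank-sum test enumerates the exact null when both groups are
    small (n <= 20) and tie-free, and otherwise uses the normal
    approximation with tie correction.  Returns (statistic, two-sided p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if test == "welch_t":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("welch_t needs n >= 2 per group")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        if np.isnan(t) and np.mean(a) == np.mean(b):  # both groups constant
            t, p = 0.0, 1.0
        return float(t), float(p)
    if test == "wilcoxon":
        if len(a) < 1 or len(b) < 1:
            raise ValueError("wilcoxon needs non-empty groups")
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


@dataclass
class RunConfig:
    """Inputs, thresholds and output location for one pipeline run."""

    annotation: str
    expression_manifest: str
    tfmap: str
    obo: str
    annotations: str
    out_dir: str | None = None
    # species: ordered list of (name, ortholog_tsv, annotation_path)
    species: list[tuple[str, str, str]] = field(default_factory=list)
    seed: int = 0
    alpha: float = 0.05
    max_distance: int = 1000
    max_overlap: int | None = 2000
    bin_edges: tuple[int, ...] = (0, 100, 200, 400, 1000)
    pcc_thresholds: tuple[float, ...] = (0.355, 0.5, 0.6)
    combine: str = "max"
    corr_method: str = "pearson"
    random_reps: int = 100
    funcsim_iterations: int = 100
    min_level_n: int = 20
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "species" in raw:
            raw["species"] = [
                (s["name"], s["orthologs"], s["annotation"]) for s in raw["species"]
            ]
        for key in ("bin_edges", "pcc_thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class StratifiedReport:
    """All tables, statistical tests and feature verdicts of one run."""

    levels: list[str]
    counts: dict[str, int]
    tables: dict[str, pd.DataFrame]
    tests: dict[str, dict]
    verdicts: dict[str, str]
    summaries: dict[str, dict]

    def to_json_dict(self) -> dict:
        return {
            "levels": self.levels,
            "counts": self.counts,
            "tests": self.tests,
            "verdicts": self.verdicts,
            "summaries": self.summaries,
        }


def _monotone(values: Sequence[float], ns: Sequence[int], direction: int,
              min_n: int) -> bool:
    """Non-strict monotonicity of per-level statistics in `direction`.

    Levels with fewer than ``min_n`` observations are ignored (their
    statistics are too noisy to falsify a trend); at least three levels
    must remain for the trend to count.
    """
    kept = [v for v, n in zip(values, ns) if n >= min_n and np.isfinite(v)]
    if len(kept) < 3:
        return False
    diffs = np.diff(kept) * direction
    return bool((diffs >= 0).all())


def _verdict(stage1_p: float, stage1_direction_ok: bool, monotone: bool,
             alpha: float) -> str:
    if stage1_p >= alpha or not stage1_direction_ok:
        return "negated"
    return "inherent" if monotone else "postponed"


def run_pipeline(config: RunConfig):
    """Execute every stage and assemble the stratified report.

    Returns the :class:`StratifiedReport`; when ``config.out_dir`` is
    set, also writes report.json, the per-table TSVs, and the resolved
    configuration.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    rng_seed = int(config.seed)

    # ---- stage: gene models -------------------------------------------------
    logger.info("stage gene_models: reading %s", config.annotation)
    genes = gm.read_annotation(config.annotation)
    if not genes:
        raise RuntimeError("stage gene_models failed: empty annotation")
    pairs = gm.detect_h2h_pairs(genes, config.max_distance, config.max_overlap)
    if not pairs:
        raise RuntimeError("stage gene_models failed: no h2h pairs detected")
    pair_set = gm.PairSet.from_h2h(pairs)
    h2h_genes = sorted({g for p in pair_set for g in p})
    logger.info("stage gene_models: %d pairs, %d genes", len(pair_set), len(h2h_genes))

    all_ids = [g.gene_id for g in genes]
    adjacent = gm.same_strand_adjacent_pairs(genes, h2h_genes)
    random_pairs = gm.sample_random_pairs(
        all_ids, n_per_rep=len(pair_set), n_reps=config.random_reps, seed=rng_seed
    )

    # ---- stage: conservation ------------------------------------------------
    species_order = [name for name, _, _ in config.species]
    ortholog_maps = {}
    species_pairs = {}
    for name, orth_path, annot_path in config.species:
        ortholog_maps[name] = cons.OrthologMap.from_table(orth_path, name)
        sp_genes = gm.read_annotation(annot_path)
        species_pairs[name] = gm.PairSet.from_h2h(
            gm.detect_h2h_pairs(sp_genes, config.max_distance, config.max_overlap),
            label=f"h2h-{name}",
        )
    assignment = cons.assign_conservation(pairs, species_order, ortholog_maps, species_pairs)
    levels = assignment.levels
    level_members = {lv: assignment.members(lv) for lv in levels}
    counts = {lv: len(level_members[lv]) for lv in levels}
    logger.info("stage conservation: level counts %s", counts)

    dist_of = {p.key: p.tss_distance for p in pairs}

    # TSS-distance table + trend on the shortest non-overlapping bin
    tss_rows = []
    for lv in levels:
        sub = [p for p in pairs if p.key in level_members[lv]]
        hist = gm.bin_tss_distances(sub, config.bin_edges)
        hist.insert(0, "level", lv)
        tss_rows.append(hist)
    tss_table = pd.concat(tss_rows, ignore_index=True)
    lo, hi = config.bin_edges[0], config.bin_edges[1]
    short_bin = f"({lo}, {hi}]"
    successes = [
        int(
            tss_table.loc[
                (tss_table["level"] == lv) & (tss_table["bin"] == short_bin), "count"
            ].iloc[0]
        )
        for lv in levels
    ]
    totals = [counts[lv] for lv in levels]
    keep = [i for i, t in enumerate(totals) if t > 0]
    if len(keep) >= 2:
        trend_nested = cons.proportion_trend_test(
            [successes[i] for i in keep], [totals[i] for i in keep],
            scores=[i + 1 for i in keep],
        )
    else:
        trend_nested = {"statistic": None, "p": None, "note": "fewer than 2 non-empty levels"}
    # disjoint complements (H\HM, ..., deepest level) as the labelled companion
    disj_succ, disj_tot = [], []
    for i, lv in enumerate(levels):
        members = level_members[lv]
        if i + 1 < len(levels):
            members = members - level_members[levels[i + 1]]
        disj_tot.append(len(members))
        disj_succ.append(sum(1 for k in members if 0 < dist_of[k] <= hi))
    if all(t > 0 for t in disj_tot):
        trend_disjoint = cons.proportion_trend_test(disj_succ, disj_tot)
    else:
        trend_disjoint = {"statistic": None, "p": None, "note": "empty complement set"}

    # ---- stage: coexpression ------------------------------------------------
    manifest = pd.read_csv(config.expression_manifest, sep="\t")
    if manifest.empty:
        raise RuntimeError("stage coexpression failed: zero datasets in manifest")
    manifest_dir = os.path.dirname(os.path.abspath(config.expression_manifest))
    datasets = [
        coex.ExpressionDataset.from_tsv(
            row.path if os.path.isabs(row.path)
            else os.path.join(manifest_dir, row.path),
            str(row.dataset_id),
        )
        for row in manifest.itertuples(index=False)
    ]
    primary = datasets[0]
    logger.info(
        "stage coexpression: %d datasets, primary %r (%d genes x %d samples)",
        len(datasets), primary.dataset_id, len(primary.genes), primary.n_samples,
    )
    ranks = coex.rank_data(primary, config.corr_method)

    per_level_tables = {}
    coexpr_rows = []
    for lv in levels:
        if not level_members[lv]:
            per_level_tables[lv] = pd.DataFrame(columns=["gene_a", "gene_b", "r"])
            coexpr_rows.append({"set": lv, "label": lv, "n_pairs": 0})
            continue
        lv_set = gm.PairSet(label=f"h2h-{lv}", pairs=sorted(level_members[lv]))
        table, summary = coex.pairset_coexpression_summary(
            lv_set, primary, config.corr_method, ranks=ranks
        )
        per_level_tables[lv] = table
        coexpr_rows.append({"set": lv, **summary})
    random_table, random_summary = coex.pairset_coexpression_summary(
        random_pairs, primary, config.corr_method, ranks=ranks
    )
    adj_table, adjacent_summary = coex.pairset_coexpression_summary(
        adjacent, primary, config.corr_method, ranks=ranks
    )
    coexpr_rows.append({"set": "random", **random_summary})
    coexpr_rows.append({"set": "adjacent", **adjacent_summary})
    coexpr_table = pd.DataFrame(coexpr_rows).drop(columns=["label"])

    # significance ratios across all datasets
    profiles = {
        key: coex.significance_profile(key, datasets, config.alpha, config.corr_method)
        for key in pair_set.keys
    }
    sig_rows = []
    for lv in levels:
        lv_profiles = [profiles[k] for k in level_members[lv]]
        sig_rows.append(
            {
                "set": lv,
                "n_pairs": len(lv_profiles),
                "mean_spr": float(np.mean([p.spr for p in lv_profiles]))
                if lv_profiles else float("nan"),
                "mean_snr": float(np.mean([p.snr for p in lv_profiles]))
                if lv_profiles else float("nan"),
                "mean_sr": float(np.mean([p.sr for p in lv_profiles]))
                if lv_profiles else float("nan"),
            }
        )
    sig_table = pd.DataFrame(sig_rows)
    random_profile_keys = list(dict.fromkeys(random_pairs.pairs))[: len(pair_set)]
    random_profiles = [
        coex.significance_profile(k, datasets, config.alpha, config.corr_method)
        for k in random_profile_keys
    ]

    # inter-pair coexpression per level
    inter_rows = []
    for lv in levels:
        lv_genes = sorted({g for k in level_members[lv] for g in k})
        if len(lv_genes) >= 3:
            inter = coex.interpair_coexpression(
                lv_genes, pair_set, primary, config.corr_method, ranks=ranks
            )
            inter_rows.append({"set": lv, **inter})
    inter_table = pd.DataFrame(inter_rows)

    # TSS distance vs coexpression (a feature the analysis expects to be absent)
    h_table = per_level_tables[levels[0]]
    h_keys = [gm.canonical_key(a, b) for a, b in zip(h_table.gene_a, h_table.gene_b)]
    dists = np.array([dist_of[k] for k in h_keys], dtype=float)
    rs = h_table["r"].to_numpy()
    ok = np.isfinite(rs)
    if ok.sum() >= 3 and np.std(dists[ok]) > 0:
        d_r, d_p = stats.pearsonr(dists[ok], rs[ok])
        distance_corr = {"r": float(d_r), "p": float(d_p), "n": int(ok.sum())}
    else:
        distance_corr = {"r": None, "p": None, "n": int(ok.sum())}

    # ---- stage: tf_regulation ----------------------------------------------
    tfmap = tfr.TFMap.from_table(config.tfmap)
    tf_rows = []
    level_share_counts = {}
    records_h = None
    for lv in levels:
        lv_set = gm.PairSet(label=f"h2h-{lv}", pairs=sorted(level_members[lv]))
        assoc = tfr.tf_associated_pairs(lv_set, tfmap)
        records = [tfr.tf_similarity(p, tfmap) for p in assoc]
        if lv == levels[0]:
            records_h = records
        n_share = sum(1 for r in records if r.n_shared >= 1)
        level_share_counts[lv] = (n_share, len(records) - n_share)
        tf_rows.append(
            {
                "set": lv,
                "n_tf_associated": len(records),
                "n_sharing": n_share,
                "n_exclusive": len(records) - n_share,
                "sharing_proportion": n_share / len(records) if records else float("nan"),
            }
        )
    adj_assoc = tfr.tf_associated_pairs(adjacent, tfmap)
    adj_records = [tfr.tf_similarity(p, tfmap) for p in adj_assoc]
    adj_share = sum(1 for r in adj_records if r.n_shared >= 1)
    tf_rows.append(
        {
            "set": "adjacent",
            "n_tf_associated": len(adj_records),
            "n_sharing": adj_share,
            "n_exclusive": len(adj_records) - adj_share,
            "sharing_proportion": adj_share / len(adj_records) if adj_records else float("nan"),
        }
    )
    tf_table = pd.DataFrame(tf_rows)
    sharing_test = tfr.sharing_proportion_test(
        level_share_counts[levels[0]], (adj_share, len(adj_records) - adj_share)
    )
    pcc_by_key = {k: float(r) for k, r in zip(h_keys, rs)}
    try:
        sharing_coexpr = tfr.sharing_vs_coexpression(records_h, pcc_by_key)
    except ValueError as exc:
        sharing_coexpr = {"error": str(exc)}
    self_reg = tfr.self_regulating_pairs(pair_set, tfmap)

    # ---- stage: go_semantics ------------------------------------------------
    dag = gos.GoDag.from_obo(config.obo)
    raw_annot = gos.AnnotationSet.from_table(config.annotations)
    propagated = gos.propagate_annotations(dag, raw_annot)
    ic = gos.information_content(dag, propagated)
    engine = gos.SemanticSimilarity(dag, ic, raw_annot, combine=config.combine)

    funcsim: dict[tuple[str, str], float | None] = {}
    per_ss: dict[str, dict[tuple[str, str], float | None]] = {
        ss: {} for ss in raw_annot.by_subsystem
    }
    for k in pair_set.keys:
        vals = {ss: engine.gene_pair(k[0], k[1], ss) for ss in raw_annot.by_subsystem}
        for ss, v in vals.items():
            per_ss[ss][k] = v
        funcsim[k] = gos.representative_similarity(vals)
    fs_rows = []
    for lv in levels:
        row = {"set": lv}
        for ss in sorted(per_ss):
            vals = [per_ss[ss][k] for k in level_members[lv] if per_ss[ss][k] is not None]
            row[f"mean_{ss}"] = float(np.mean(vals)) if vals else float("nan")
            row[f"n_{ss}"] = len(vals)
        rep = [funcsim[k] for k in level_members[lv] if funcsim[k] is not None]
        row["mean_representative"] = float(np.mean(rep)) if rep else float("nan")
        row["n_representative"] = len(rep)
        fs_rows.append(row)
    funcsim_table = pd.DataFrame(fs_rows)

    h_rep = [funcsim[k] for k in level_members[levels[0]] if funcsim[k] is not None]
    null_means = gos.random_funcsim_control(
        engine, n_pairs=max(len(h_rep), 2), n_iter=config.funcsim_iterations,
        seed=rng_seed + 7,
    )
    # stage-1 comparison: observed pairs vs one null-sized sample of random pairs
    rng = np.random.default_rng(rng_seed + 11)
    annotated_genes = sorted(
        {g for genes_ in raw_annot.by_subsystem.values() for g in genes_}
    )
    random_rep: list[float] = []
    attempts = 0
    while len(random_rep) < len(h_rep) and attempts < 100 * max(len(h_rep), 1):
        attempts += 1
        i, j = rng.integers(0, len(annotated_genes), size=2)
        if i == j:
            continue
        v = engine.representative(annotated_genes[i], annotated_genes[j])
        if v is not None:
            random_rep.append(v)
    funcsim_stat, funcsim_p = compare_groups(h_rep, random_rep, "wilcoxon")

    rep_pairs = [k for k in pair_set.keys if funcsim[k] is not None and k in pcc_by_key]
    fs_vals = np.array([funcsim[k] for k in rep_pairs])
    fs_pcc = np.array([pcc_by_key[k] for k in rep_pairs])
    if len(rep_pairs) >= 3 and np.std(fs_vals) > 0 and np.std(fs_pcc) > 0:
        fr, fp = stats.pearsonr(fs_vals, fs_pcc)
        funcsim_pcc_corr = {"r": float(fr), "p": float(fp), "n": len(rep_pairs)}
    else:
        funcsim_pcc_corr = {"r": None, "p": None, "n": len(rep_pairs)}
    thr_rows = []
    for lv in levels:
        thr = gos.funcsim_by_coexpression_threshold(
            sorted(level_members[lv]), funcsim, pcc_by_key, config.pcc_thresholds
        )
        thr.insert(0, "set", lv)
        thr_rows.append(thr)
    threshold_table = pd.concat(thr_rows, ignore_index=True)

    # ---- verdicts -----------------------------------------------------------
    alpha = config.alpha
    tests: dict[str, dict] = {}
    verdicts: dict[str, str] = {}

    # positive coexpression: h2h vs random pairs, increasing with conservation
    h_r = per_level_tables[levels[0]]["r"].to_numpy()
    rand_vals = random_table["r"].to_numpy()
    stat, p = compare_groups(h_r, rand_vals, "welch_t")
    level_means = [
        float(np.nanmean(per_level_tables[lv]["r"]))
        if len(per_level_tables[lv]) else float("nan")
        for lv in levels
    ]
    mono = _monotone(level_means, totals, direction=+1, min_n=config.min_level_n)
    tests["positive_coexpression_vs_random"] = {
        "test": "welch_t", "statistic": stat, "p": p,
        "n_a": len(h_r), "n_b": len(rand_vals),
        "level_means": dict(zip(levels, level_means)), "monotone_increasing": mono,
    }
    verdicts["positive_coexpression"] = _verdict(p, stat > 0, mono, alpha)

    # negative coexpression: claimed direction is *more* significant negative
    # correlation than random pairs
    h_snr = [profiles[k].snr for k in level_members[levels[0]]]
    rand_snr = [pr.snr for pr in random_profiles]
    stat_n, p_n = compare_groups(h_snr, rand_snr, "welch_t")
    snr_means = sig_table["mean_snr"].tolist()
    mono_n = _monotone(snr_means, totals, direction=+1, min_n=config.min_level_n)
    tests["negative_coexpression_vs_random"] = {
        "test": "welch_t", "statistic": stat_n, "p": p_n,
        "n_a": len(h_snr), "n_b": len(rand_snr),
        "level_means": dict(zip(levels, snr_means)), "monotone_increasing": mono_n,
    }
    verdicts["negative_coexpression"] = _verdict(p_n, stat_n > 0, mono_n, alpha)

    # TF sharing: proportion vs adjacent control, increasing with conservation
    tf_props = [
        level_share_counts[lv][0] / sum(level_share_counts[lv])
        if sum(level_share_counts[lv]) else float("nan")
        for lv in levels
    ]
    tf_ns = [sum(level_share_counts[lv]) for lv in levels]
    mono_tf = _monotone(tf_props, tf_ns, direction=+1, min_n=config.min_level_n)
    tests["tf_sharing_vs_adjacent"] = {
        "test": "chi2_2x2", **sharing_test,
        "level_proportions": dict(zip(levels, tf_props)),
        "monotone_increasing": mono_tf,
    }
    verdicts["tf_sharing"] = _verdict(
        sharing_test["p_two_sided"],
        sharing_test["proportion_focal"] > sharing_test["proportion_control"],
        mono_tf, alpha,
    )

    # functional similarity: h2h vs random annotated pairs, increasing
    fs_means = funcsim_table["mean_representative"].tolist()
    fs_ns = funcsim_table["n_representative"].tolist()
    mono_fs = _monotone(fs_means, fs_ns, direction=+1, min_n=config.min_level_n)
    tests["functional_similarity_vs_random"] = {
        "test": "wilcoxon", "statistic": funcsim_stat, "p": funcsim_p,
        "n_a": len(h_rep), "n_b": len(random_rep),
        "null_mean": float(np.mean(null_means)),
        "null_q95": float(np.quantile(null_means, 0.95)),
        "observed_mean": float(np.mean(h_rep)) if h_rep else None,
        "level_means": dict(zip(levels, fs_means)), "monotone_increasing": mono_fs,
    }
    fs_dir_ok = bool(h_rep) and float(np.mean(h_rep)) > float(np.mean(random_rep))
    verdicts["functional_similarity"] = _verdict(funcsim_p, fs_dir_ok, mono_fs, alpha)

    tests["tss_distance_trend_short_bin"] = {
        "test": "cochran_armitage", "bin": short_bin,
        "successes": successes, "totals": totals, **trend_nested,
        "disjoint_sets": {"successes": disj_succ, "totals": disj_tot,
                          **{k: v for k, v in trend_disjoint.items() if k != "scores"}},
    }
    tests["tss_distance_vs_coexpression"] = {
        "test": "pearson", **distance_corr,
    }
    tests["tf_sharing_vs_coexpression"] = sharing_coexpr
    tests["funcsim_vs_coexpression"] = {"test": "pearson", **funcsim_pcc_corr}

    report = StratifiedReport(
        levels=levels,
        counts=counts,
        tables={
            "table1_tss": tss_table,
            "table2_sigratio": sig_table,
            "table3_tf": tf_table,
            "table5_funcsim": funcsim_table,
            "table6_thresholds": threshold_table,
            "coexpression_summary": coexpr_table,
            "interpair_coexpression": inter_table,
            "self_regulating_pairs": self_reg,
        },
        tests=tests,
        verdicts=verdicts,
        summaries={
            "coexpression": {r["set"]: r for r in coexpr_rows},
            "significance": {r["set"]: r for r in sig_rows},
        },
    )

    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        for name, table in report.tables.items():
            table.to_csv(os.path.join(config.out_dir, f"{name}.tsv"),
                         sep="\t", index=False)
        with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=2, default=_jsonable)
        with open(os.path.join(config.out_dir, "run_config.json"), "w") as fh:
            json.dump(dataclasses.asdict(config), fh, indent=2, default=str)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
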