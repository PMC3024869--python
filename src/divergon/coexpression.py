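"""Pair coexpression statistics: correlations, mutual ranks, significance ratios.

Given expression matrices (genes x samples), this module computes, for
gene pairs:

* Pearson / Spearman correlation coefficients with two-sided p-values
  from the t transform ``t = r * sqrt((n-2) / (1-r^2))`` on n-2 df;
* reciprocal correlation ranks Rank(A->B) (the 1-based position of B in
  A's neighbour list sorted by descending correlation), and from them the
  Mutual Rank ``MR = sqrt(Rank(A->B) * Rank(B->A))`` (geometric mean) and
  the Relative Rank ``RR = min(Rank(A->B), Rank(B->A))`` — low values of
  either mean strong mutual coexpression;
* multi-dataset significance ratios: the fraction of datasets in which a
  pair is significantly positively (SPR), negatively (SNR), or at all
  (SR) correlated, with SPR + SNR = SR by construction;
* set-level summaries for pair sets and for all inter-pair combinations
  among a gene set with the actual pairs excluded.

Ties in the rank lists are broken by ascending gene id so every rank is
a deterministic integer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gene_models import PairSet, canonical_key

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "CorrelationResult",
    "RankPair",
    "RankData",
    "SignificanceProfile",
    "correlate",
    "rank_lists",
    "rank_data",
    "mutual_rank",
    "significance_profile",
    "pairset_coexpression_summary",
    "interpair_coexpression",
]

METHODS = ("pearson", "spearman")


@dataclass
class ExpressionDataset:
    """One genes x samples expression matrix with a dataset id."""

    dataset_id: str
    values: pd.DataFrame  # index: gene ids; columns: sample ids

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError(f"dataset {self.dataset_id!r}: duplicate gene rows")
        if self.values.shape[1] < 3:
            raise ValueError(f"dataset {self.dataset_id!r}: need >= 3 samples")
        finite = np.isfinite(self.values.to_numpy(dtype=float)).sum(axis=1)
        if (finite < 3).any():
            bad = self.values.index[finite < 3].tolist()
            raise ValueError(
                f"dataset {self.dataset_id!r}: rows with < 3 finite values: {bad[:5]}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def __contains__(self, gene: str) -> bool:
        return gene in self.values.index

    @classmethod
    def from_tsv(cls, path: str, dataset_id: str | None = None) -> "ExpressionDataset":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(dataset_id=dataset_id or str(path), values=df)

    def to_tsv(self, path: str) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str
    undefined: bool = False


@dataclass(frozen=True)
class RankPair:
    """Reciprocal ranks of a pair with the derived MR and RR indices."""

    rank_ab: int
    rank_ba: int

    @property
    def mr(self) -> float:
        return math.sqrt(self.rank_ab * self.rank_ba)

    @property
    def rr(self) -> int:
        return min(self.rank_ab, self.rank_ba)


@dataclass(frozen=True)
class SignificanceProfile:
    """Fractions of datasets with significant (positive/negative) correlation."""

    spr: float
    snr: float
    sr: float
    n_datasets_used: int

    @classmethod
    def from_counts(cls, n_positive: int, n_negative: int, n_datasets: int):
        if n_datasets <= 0:
            raise ValueError("need at least one usable dataset")
        return cls(
            spr=n_positive / n_datasets,
            snr=n_negative / n_datasets,
            sr=(n_positive + n_negative) / n_datasets,
            n_datasets_used=n_datasets,
        )


def _p_from_t(r: float, n: int) -> float:
    """Two-sided p-value for a correlation via the t transform (n-2 df)."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> CorrelationResult:
    """Correlate two sample vectors with pairwise-complete deletion.

    Positions missing (non-finite) in either vector are dropped; at least
    3 complete positions are required.  A zero-variance vector yields an
    undefined-correlation flag (r and p are NaN) rather than an error, so
    callers can exclude the pair downstream.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete sample pairs, got {n}")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(math.nan, math.nan, n, method, undefined=True)
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-12:  # exact linear dependence up to rounding
        r = math.copysign(1.0, r)
    return CorrelationResult(r, _p_from_t(r, n), n, method)


# ---------------------------------------------------------------------------
# Rank machinery
# ---------------------------------------------------------------------------

def _correlation_matrix(dataset: ExpressionDataset, method: str) -> np.ndarray:
    X = dataset.values.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        # pairwise-complete fallback; adequate for the modest matrices it serves
        return dataset.values.T.corr(method=method).to_numpy()
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = dataset.genes[sd == 0].tolist()
        raise ValueError(
            f"dataset {dataset.dataset_id!r}: zero-variance rows {bad[:5]}"
        )
    return np.corrcoef(X)


@dataclass
class RankData:
    """Dense reciprocal-rank matrix for one dataset.

    ``ranks[i, j]`` is Rank(gene_i -> gene_j): the 1-based position of j
    in i's neighbour list ordered by descending correlation, ties broken
    by ascending gene id.  The diagonal is 0 (a gene is not its own
    neighbour).
    """

    genes: pd.Index
    corr: np.ndarray
    ranks: np.ndarray

    def index_of(self, gene: str) -> int:
        try:
            return self.genes.get_loc(gene)
        except KeyError:
            raise KeyError(f"gene {gene!r} not in dataset") from None

    def rank(self, a: str, b: str) -> int:
        return int(self.ranks[self.index_of(a), self.index_of(b)])


def rank_data(dataset: ExpressionDataset, method: str = "pearson") -> RankData:
    """Compute the full correlation and reciprocal-rank matrices."""
    if len(dataset.genes) < 3:
        raise ValueError("need >= 3 genes to build rank lists")
    C = _correlation_matrix(dataset, method)
    G = len(dataset.genes)
    id_rank = np.empty(G, dtype=np.int64)
    id_rank[np.argsort(np.asarray(dataset.genes))] = np.arange(G)
    ranks = np.zeros((G, G), dtype=np.int32)
    cols = np.arange(G)
    for i in range(G):
        row = C[i].copy()
        row[i] = np.inf  # self sorts first, then gets dropped
        order = np.lexsort((id_rank, -row))
        order = order[order != i]
        ranks[i, order] = np.arange(1, G, dtype=np.int32)
    return RankData(genes=dataset.genes, corr=C, ranks=ranks)


def rank_lists(dataset: ExpressionDataset, method: str = "pearson") -> dict[str, list[str]]:
    """Per-gene neighbour lists ordered by descending correlation.

    Rank(A->B) is the 1-based position of B in the returned list for A.
    Intended for small matrices; large runs use :func:`rank_data` directly.
    """
    rd = rank_data(dataset, method)
    out: dict[str, list[str]] = {}
    genes = np.asarray(rd.genes)
    for i, g in enumerate(genes):
        order = np.argsort(rd.ranks[i])
        order = order[rd.ranks[i][order] > 0]
        out[g] = [str(x) for x in genes[order]]
    return out


def mutual_rank(pair: tuple[str, str], ranks: RankData) -> RankPair:
    """Reciprocal ranks + MR/RR for one gene pair."""
    a, b = pair
    return RankPair(rank_ab=ranks.rank(a, b), rank_ba=ranks.rank(b, a))


# ---------------------------------------------------------------------------
# Multi-dataset significance ratios
# ---------------------------------------------------------------------------

def significance_profile(
    pair: tuple[str, str],
    datasets: Iterable[ExpressionDataset],
    alpha: float = 0.05,
    method: str = "pearson",
) -> SignificanceProfile:
    """SPR / SNR / SR of a pair across a dataset collection.

    A dataset is usable when it contains both genes with >= 3 complete
    sample pairs and defined correlation; unmeasured datasets are
    excluded from the denominator so SPR + SNR = SR holds exactly.
    """
    a, b = pair
    n_pos = n_neg = used = 0
    for ds in datasets:
        if a not in ds or b not in ds:
            continue
        xa = ds.values.loc[a].to_numpy(dtype=float)
        xb = ds.values.loc[b].to_numpy(dtype=float)
        ok = np.isfinite(xa) & np.isfinite(xb)
        if ok.sum() < 3:
            continue
        res = correlate(xa[ok], xb[ok], method)
        if res.undefined:
            continue
        used += 1
        if res.p < alpha:
            if res.r > 0:
                n_pos += 1
            elif res.r < 0:
                n_neg += 1
    if used == 0:
        raise ValueError(f"pair {pair}: no usable dataset")
    return SignificanceProfile.from_counts(n_pos, n_neg, used)


# ---------------------------------------------------------------------------
# Set-level summaries
# ---------------------------------------------------------------------------

def _pair_correlations(
    dataset: ExpressionDataset, pairs: Sequence[tuple[str, str]], method: str
) -> np.ndarray:
    """Vectorised per-pair correlations (complete data fast path)."""
    X = dataset.values.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        return np.array(
            [
                correlate(dataset.values.loc[a], dataset.values.loc[b], method).r
                for a, b in pairs
            ]
        )
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = (X - mu) / np.where(sd == 0, np.nan, sd)
    loc = {g: i for i, g in enumerate(dataset.genes)}
    ia = np.array([loc[a] for a, _ in pairs])
    ib = np.array([loc[b] for _, b in pairs])
    r = (Z[ia] * Z[ib]).mean(axis=1)
    return np.clip(r, -1.0, 1.0)


def pairset_coexpression_summary(
    pair_set: PairSet,
    dataset: ExpressionDataset,
    method: str = "pearson",
    ranks: RankData | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-pair correlation (and MR/RR when ranks are given) plus set means.

    Pairs with a gene absent from the dataset are skipped with a logged
    count; an all-skipped set is an error.  Returns the per-pair table and
    a summary dict with mean/median of each available index.
    """
    usable = [p for p in pair_set if p[0] in dataset and p[1] in dataset]
    skipped = len(pair_set) - len(usable)
    if skipped:
        logger.info(
            "pair set %r: skipped %d pairs absent from dataset %r",
            pair_set.label, skipped, dataset.dataset_id,
        )
    if not usable:
        raise ValueError(f"pair set {pair_set.label!r}: no pair measured in dataset")
    r = _pair_correlations(dataset, usable, method)
    table = pd.DataFrame(
        {
            "gene_a": [a for a, _ in usable],
            "gene_b": [b for _, b in usable],
            "r": r,
        }
    )
    if ranks is not None:
        rps = [mutual_rank(p, ranks) for p in usable]
        table["rank_ab"] = [rp.rank_ab for rp in rps]
        table["rank_ba"] = [rp.rank_ba for rp in rps]
        table["mr"] = [rp.mr for rp in rps]
        table["rr"] = [rp.rr for rp in rps]
    summary = {
        "label": pair_set.label,
        "n_pairs": len(usable),
        "n_skipped": skipped,
        "mean_r": float(np.nanmean(r)),
        "median_r": float(np.nanmedian(r)),
    }
    if ranks is not None:
        summary["mean_mr"] = float(table["mr"].mean())
        summary["median_mr"] = float(table["mr"].median())
        summary["mean_rr"] = float(table["rr"].mean())
        summary["median_rr"] = float(table["rr"].median())
    return table, summary


def interpair_coexpression(
    h2h_genes: Iterable[str],
    actual_pairs: PairSet,
    dataset: ExpressionDataset,
    method: str = "pearson",
    ranks: RankData | None = None,
) -> dict:
    """Coexpression among all cross pairs of a gene set, actual pairs excluded.

    Enumerates every unordered pair within ``h2h_genes`` that is measured
    in the dataset, removes the canonical keys of ``actual_pairs``, and
    summarises PCC (and MR if ranks are supplied) over what remains.
    """
    genes = sorted(set(h2h_genes))
    if len(genes) < 3:
        raise ValueError("need >= 3 genes for inter-pair analysis")
    present = [g for g in genes if g in dataset]
    loc = (
        ranks.genes if ranks is not None else dataset.genes
    ).get_indexer(present)
    C = ranks.corr if ranks is not None else _correlation_matrix(dataset, method)
    sub = C[np.ix_(loc, loc)]
    iu = np.triu_indices(len(present), k=1)
    keep = np.ones(len(iu[0]), dtype=bool)
    actual = actual_pairs.keys
    for k, (i, j) in enumerate(zip(*iu)):
        if canonical_key(present[i], present[j]) in actual:
            keep[k] = False
    r = sub[iu][keep]
    out = {
        "n_genes": len(present),
        "n_pairs": int(keep.sum()),
        "n_excluded": int((~keep).sum()),
        "mean_r": float(np.nanmean(r)),
        "median_r": float(np.nanmedian(r)),
    }
    if ranks is not None:
        R = ranks.ranks[np.ix_(loc, loc)].astype(float)
        mr = np.sqrt(R[iu] * R.T[iu])[keep]
        out["mean_mr"] = float(np.mean(mr))
        out["median_mr"] = float(np.median(mr))
    return out
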