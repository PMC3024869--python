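"""Transcription-factor sharing analysis for head-to-head pairs.

Divergent gene pairs that share a bidirectional promoter are expected to
be reached by common transcription factors.  Given a TF -> target map,
this module restricts a pair set to pairs whose two genes are both
TF-associated, computes the TF similarity of each pair (shared TFs over
the union of TFs, a Jaccard index), classifies pairs as sharing no, one,
or several TFs, compares the sharing proportion against a control set
with a 2x2 chi-squared test, flags pairs in which one gene is itself a
TF regulating its partner, and relates TF sharing to coexpression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .gene_models import PairSet

logger = logging.getLogger(__name__)

__all__ = [
    "TFMap",
    "SharingRecord",
    "tf_associated_pairs",
    "tf_similarity",
    "sharing_proportion_test",
    "self_regulating_pairs",
    "sharing_vs_coexpression",
]

CLASSES = ("no-share", "one-share", "multi-share")


@dataclass
class TFMap:
    """Gene -> set of regulating TFs, with the derived inverse map."""

    targets: dict[str, frozenset[str]]

    @property
    def inverse(self) -> dict[str, set[str]]:
        inv: dict[str, set[str]] = {}
        for gene, tfs in self.targets.items():
            for tf in tfs:
                inv.setdefault(tf, set()).add(gene)
        return inv

    def tfs_of(self, gene: str) -> frozenset[str]:
        return self.targets.get(gene, frozenset())

    @classmethod
    def from_table(cls, path: str) -> "TFMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["tf", "target"], dtype=str)
        targets: dict[str, set[str]] = {}
        for tf, target in df.itertuples(index=False):
            targets.setdefault(target, set()).add(tf)
        return cls(targets={g: frozenset(t) for g, t in targets.items()})

    def to_table(self, path: str) -> None:
        rows = [
            (tf, gene)
            for gene, tfs in sorted(self.targets.items())
            for tf in sorted(tfs)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class SharingRecord:
    """TF sharing of one pair: shared / union counts, Jaccard, class label."""

    pair: tuple[str, str]
    n_shared: int
    n_union: int

    @property
    def tf_similarity(self) -> float:
        return self.n_shared / self.n_union if self.n_union else 0.0

    @property
    def sharing_class(self) -> str:
        if self.n_shared == 0:
            return "no-share"
        return "one-share" if self.n_shared == 1 else "multi-share"


def tf_associated_pairs(pairs: PairSet, tfmap: TFMap) -> PairSet:
    """Subset of pairs in which both genes have at least one associated TF."""
    kept = [p for p in pairs if tfmap.tfs_of(p[0]) and tfmap.tfs_of(p[1])]
    return PairSet(label=f"{pairs.label}-tf", pairs=kept, unique=pairs.unique)


def tf_similarity(pair: tuple[str, str], tfmap: TFMap) -> SharingRecord:
    """Jaccard TF similarity of a TF-associated pair."""
    ta, tb = tfmap.tfs_of(pair[0]), tfmap.tfs_of(pair[1])
    if not ta or not tb:
        raise ValueError(f"pair {pair}: both genes must be TF-associated")
    return SharingRecord(pair=pair, n_shared=len(ta & tb), n_union=len(ta | tb))


def sharing_proportion_test(
    focal: tuple[int, int], control: tuple[int, int], correction: bool = False
) -> dict:
    """Compare TF-sharing proportions between two pair sets (2x2 chi-squared).

    Each argument is (n_sharing, n_exclusive).  The Pearson chi-squared
    (optionally Yates-corrected) two-sided p is reported together with a
    one-sided p for the focal-greater direction.
    """
    (s1, e1), (s2, e2) = focal, control
    if min(s1, e1, s2, e2) < 0:
        raise ValueError("counts must be non-negative")
    if s1 + e1 == 0 or s2 + e2 == 0:
        raise ValueError("both sets must be non-empty")
    table = np.array([[s1, e1], [s2, e2]], dtype=float)
    p1, p2 = s1 / (s1 + e1), s2 / (s2 + e2)
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0 or p1 == p2:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    one_sided = p / 2 if p1 >= p2 else 1 - p / 2
    return {
        "proportion_focal": p1,
        "proportion_control": p2,
        "chi2": float(chi2),
        "p_two_sided": float(p),
        "p_one_sided_focal_greater": float(one_sided),
    }


def self_regulating_pairs(pairs: PairSet, tfmap: TFMap) -> pd.DataFrame:
    """Pairs in which one gene is a TF regulating the other.

    Returns one row per such pair with the direction(s); mutual
    regulation yields both directions.
    """
    rows = []
    for a, b in pairs:
        directions = []
        if a in tfmap.tfs_of(b):
            directions.append(f"{a}->{b}")
        if b in tfmap.tfs_of(a):
            directions.append(f"{b}->{a}")
        if directions:
            rows.append({"gene_a": a, "gene_b": b, "directions": ";".join(directions)})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "directions"])


def sharing_vs_coexpression(
    records: Iterable[SharingRecord], pcc: Mapping[tuple[str, str], float]
) -> dict:
    """Relate TF-sharing class and TF similarity to pair coexpression.

    Computes per-class mean PCC, Welch t-tests for (any sharing vs no
    sharing) and (multi vs one shared TF), and the Pearson correlation of
    TF similarity with PCC over the sharing pairs.  A constant similarity
    vector leaves the correlation undefined (flagged, not an error).
    """
    records = [rec for rec in records if rec.pair in pcc]
    groups: dict[str, list[float]] = {c: [] for c in CLASSES}
    for rec in records:
        groups[rec.sharing_class].append(pcc[rec.pair])

    def _welch(a, b, name_a, name_b):
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                f"groups too small for t-test: {name_a} (n={len(a)}), {name_b} (n={len(b)})"
            )
        t, p = stats.ttest_ind(a, b, equal_var=False)
        if np.isnan(t) and np.mean(a) == np.mean(b):  # both groups constant
            t, p = 0.0, 1.0
        return {"t": float(t), "p": float(p), "n_a": len(a), "n_b": len(b)}

    sharing = groups["one-share"] + groups["multi-share"]
    out = {
        "class_means": {
            c: (float(np.mean(v)) if v else None) for c, v in groups.items()
        },
        "class_n": {c: len(v) for c, v in groups.items()},
        "test_sharing_vs_none": _welch(sharing, groups["no-share"], "sharing", "no-share"),
        "test_multi_vs_one": _welch(
            groups["multi-share"], groups["one-share"], "multi-share", "one-share"
        ),
    }
    sims = np.array([r.tf_similarity for r in records if r.n_shared >= 1])
    vals = np.array([pcc[r.pair] for r in records if r.n_shared >= 1])
    if len(sims) >= 3 and np.std(sims) > 0 and np.std(vals) > 0:
        rho, p = stats.pearsonr(sims, vals)
        out["similarity_pcc_correlation"] = {"r": float(rho), "p": float(p), "n": len(sims)}
    else:
        out["similarity_pcc_correlation"] = {"r": None, "p": None, "n": len(sims),
                                             "undefined": True}
    return out
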