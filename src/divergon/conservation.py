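"""Nested conservation sets for head-to-head pairs and the trend test.

Human h2h pairs are stratified into sequentially inclusive sets of
increasing evolutionary conservation: all pairs (H), pairs whose ortholog
pair is also head-to-head in mouse (HM), in mouse and chicken (HMC), and
in mouse, chicken and fugu (HMCF).  Conservation is sequential (prefix
based): a pair belongs to a level only if it is conserved in *every*
species up to that point of the phylogeny, so the sets are nested by
construction.

`proportion_trend_test` is the Cochran–Armitage chi-squared test for a
linear trend in proportions across ordered groups (1 df), used to test
whether e.g. the fraction of pairs with a short bidirectional promoter
rises with conservation level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gene_models import H2HPair, PairSet, canonical_key

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologMap",
    "ConservationAssignment",
    "level_labels",
    "assign_conservation",
    "proportion_trend_test",
]


@dataclass
class OrthologMap:
    """One-to-one ortholog mapping from focal genes to a partner species.

    Many-to-many entries in the raw table are dropped (with a logged
    count) so the retained mapping is one-to-one.
    """

    species: str
    mapping: dict[str, str]

    @classmethod
    def from_table(cls, path: str, species: str) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["focal", "partner"], dtype=str)
        return cls.from_pairs(list(df.itertuples(index=False)), species)

    @classmethod
    def from_pairs(cls, rows: Iterable[tuple[str, str]], species: str) -> "OrthologMap":
        rows = list(rows)
        focal_counts = pd.Series([r[0] for r in rows]).value_counts()
        partner_counts = pd.Series([r[1] for r in rows]).value_counts()
        keep = {}
        dropped = 0
        for focal, partner in rows:
            if focal_counts[focal] > 1 or partner_counts[partner] > 1:
                dropped += 1
                continue
            keep[focal] = partner
        if dropped:
            logger.info(
                "%s orthologs: dropped %d many-to-many entries", species, dropped
            )
        return cls(species=species, mapping=keep)


@dataclass
class ConservationAssignment:
    """Per-pair conservation level, with nested level membership."""

    levels: list[str]  # ordered, least to most conserved (e.g. H..HMCF)
    by_pair: dict[tuple[str, str], str]

    def depth(self, key: tuple[str, str]) -> int:
        return self.levels.index(self.by_pair[key])

    def members(self, level: str) -> set[tuple[str, str]]:
        """Pairs at `level` or deeper (the sets are inclusive/nested)."""
        cut = self.levels.index(level)
        return {k for k, lv in self.by_pair.items() if self.levels.index(lv) >= cut}

    def counts(self) -> dict[str, int]:
        return {lv: len(self.members(lv)) for lv in self.levels}


def level_labels(species_order: Sequence[str]) -> list[str]:
    """Nested level names: H, then H + one initial per conserved species."""
    labels = ["H"]
    for i in range(len(species_order)):
        labels.append("H" + "".join(s[0].upper() for s in species_order[: i + 1]))
    return labels


def assign_conservation(
    pairs: Iterable[H2HPair],
    species_order: Sequence[str],
    ortholog_maps: Mapping[str, OrthologMap],
    species_pairs: Mapping[str, PairSet],
) -> ConservationAssignment:
    """Assign each pair the deepest conserved prefix of the species order.

    A pair is conserved in species S when both genes have (one-to-one)
    orthologs in S and those orthologs themselves form an h2h pair there.
    The level is determined by the longest prefix of ``species_order``
    within which the pair is conserved in every species — conservation in
    a distant species does not count unless all closer species agree,
    which is what makes the level sets sequentially inclusive.
    """
    for sp in species_order:
        if sp not in ortholog_maps:
            raise KeyError(f"species {sp!r} missing an ortholog map")
        if sp not in species_pairs:
            raise KeyError(f"species {sp!r} missing an h2h pair set")
    labels = level_labels(species_order)
    keysets = {sp: species_pairs[sp].keys for sp in species_order}
    by_pair: dict[tuple[str, str], str] = {}
    for pair in pairs:
        depth = 0
        for sp in species_order:
            m = ortholog_maps[sp].mapping
            a, b = pair.minus_gene, pair.plus_gene
            if a not in m or b not in m:
                break
            if canonical_key(m[a], m[b]) not in keysets[sp]:
                break
            depth += 1
        by_pair[pair.key] = labels[depth]
    return ConservationAssignment(levels=labels, by_pair=by_pair)


def proportion_trend_test(
    successes: Sequence[int],
    totals: Sequence[int],
    scores: Sequence[float] | None = None,
) -> dict:
    """Cochran–Armitage chi-squared test for trend in proportions (1 df).

    With group scores s_i (default 1..k), success counts r_i and totals
    n_i, the statistic is T^2 / Var(T) with T = sum s_i (r_i - n_i pbar)
    and Var(T) = pbar (1-pbar) [sum n_i s_i^2 - (sum n_i s_i)^2 / N].
    Returns the statistic, df=1 and the upper-tail p-value.  For k=2 this
    reduces to the ordinary 2x2 Pearson chi-squared without continuity
    correction.
    """
    r = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if r.shape != n.shape or r.ndim != 1 or len(r) < 2:
        raise ValueError("successes and totals must be equal-length 1-d, k >= 2")
    if (n <= 0).any():
        raise ValueError("all group totals must be positive")
    if ((r < 0) | (r > n)).any():
        raise ValueError("need 0 <= successes <= totals")
    s = np.arange(1, len(r) + 1, dtype=float) if scores is None else np.asarray(scores, float)
    if s.shape != r.shape:
        raise ValueError("scores must match group count")
    N = n.sum()
    pbar = r.sum() / N
    t = float(np.sum(s * (r - n * pbar)))
    var = pbar * (1 - pbar) * (np.sum(n * s**2) - np.sum(n * s) ** 2 / N)
    if var == 0:
        stat = 0.0
    else:
        stat = t * t / var
    p = float(stats.chi2.sf(stat, df=1))
    return {"statistic": stat, "df": 1, "p": p, "scores": s.tolist()}
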