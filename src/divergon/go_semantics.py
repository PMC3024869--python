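"""Information-content semantic similarity on an ontology DAG.

Implements the classic corpus-based term similarity used for functional
comparison of gene pairs:

* annotations are propagated to all ancestors (true-path rule), so the
  probability of a term, ``p(t)``, is the fraction of the subsystem's
  annotated genes covered by ``t`` after propagation, and its information
  content is ``IC(t) = -ln p(t)`` (roots have IC 0);
* the minimum subsumer of two terms is their common ancestor of maximal
  IC; its IC is the Resnik similarity of the terms (in nats);
* the Lin similarity normalises Resnik to [0, 1]:
  ``2 * IC_ms / (IC(t1) + IC(t2))``, defined as 0 when both ICs are 0;
* gene-level similarity combines the term-level values over the cross
  pairs of the two genes' direct annotations (max by default, best-match
  average and mean as alternatives), per subsystem (BP / MF / CC), and
  the representative similarity of a gene pair is the max over the
  subsystems in which both genes are annotated.

Only ``is_a`` edges are honoured, which keeps each subsystem a single
rooted DAG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GoDag",
    "AnnotationSet",
    "TermIC",
    "propagate_annotations",
    "information_content",
    "minimum_subsumer",
    "lin_similarity",
    "SemanticSimilarity",
    "gene_pair_similarity",
    "representative_similarity",
    "funcsim_by_coexpression_threshold",
    "random_funcsim_control",
]

SUBSYSTEMS = ("BP", "MF", "CC")
_NAMESPACE_TO_SUBSYSTEM = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
}
COMBINE_RULES = ("max", "bma", "mean")


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies or annotations."""


@dataclass
class GoDag:
    """An is_a ontology DAG with one root per subsystem.

    ``parents`` maps each term to its direct is_a parents; every non-root
    term must reach exactly one subsystem root, and the graph must be
    acyclic (both validated on construction).
    """

    parents: dict[str, frozenset[str]]
    subsystem: dict[str, str]
    _ancestors: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, ps in self.parents.items():
            for p in ps:
                if p not in self.parents:
                    raise OntologyError(f"term {child!r} has unknown parent {p!r}")
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            raise OntologyError("ontology contains an is_a cycle")
        roots = {t for t, ps in self.parents.items() if not ps}
        for t in self.parents:
            anc = self.ancestors(t)
            t_roots = (anc | {t}) & roots
            if len(t_roots) != 1:
                raise OntologyError(
                    f"term {t!r} reaches {len(t_roots)} subsystem roots"
                )
            root = next(iter(t_roots))
            if self.subsystem[t] != self.subsystem[root]:
                raise OntologyError(
                    f"term {t!r} namespace differs from its root {root!r}"
                )

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    @property
    def roots(self) -> dict[str, str]:
        """Subsystem label -> root term."""
        return {
            self.subsystem[t]: t for t, ps in self.parents.items() if not ps
        }

    def ancestors(self, term: str) -> frozenset[str]:
        """All strict is_a ancestors (direct and indirect) of a term."""
        if term not in self.parents:
            raise OntologyError(f"unknown term {term!r}")
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents[t])
        result = frozenset(out)
        self._ancestors[term] = result
        return result

    @classmethod
    def from_obo(cls, path: str) -> "GoDag":
        """Load an OBO 1.2 file, honouring [Term] id/namespace/is_a only."""
        import obonet

        graph = obonet.read_obo(path)
        parents: dict[str, set[str]] = {}
        subsystem: dict[str, str] = {}
        for term, data in graph.nodes(data=True):
            parents.setdefault(term, set())
            ns = data.get("namespace", "")
            if ns not in _NAMESPACE_TO_SUBSYSTEM:
                raise OntologyError(f"term {term!r} has unknown namespace {ns!r}")
            subsystem[term] = _NAMESPACE_TO_SUBSYSTEM[ns]
        for child, parent, key in graph.edges(keys=True):
            if key == "is_a":
                parents[child].add(parent)
        return cls(
            parents={t: frozenset(ps) for t, ps in parents.items()},
            subsystem=subsystem,
        )


@dataclass
class AnnotationSet:
    """Gene -> term annotations, partitioned by subsystem."""

    by_subsystem: dict[str, dict[str, frozenset[str]]]
    propagated: bool = False

    def genes(self, subsystem: str) -> set[str]:
        return set(self.by_subsystem.get(subsystem, {}))

    def terms_of(self, gene: str, subsystem: str) -> frozenset[str]:
        return self.by_subsystem.get(subsystem, {}).get(gene, frozenset())

    @classmethod
    def from_table(cls, path: str) -> "AnnotationSet":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["gene_id", "term_id", "subsystem"],
            dtype=str,
        )
        by_ss: dict[str, dict[str, set[str]]] = {}
        for gene, term, ss in df.itertuples(index=False):
            by_ss.setdefault(ss, {}).setdefault(gene, set()).add(term)
        return cls(
            by_subsystem={
                ss: {g: frozenset(ts) for g, ts in genes.items()}
                for ss, genes in by_ss.items()
            }
        )

    def to_table(self, path: str) -> None:
        rows = [
            (g, t, ss)
            for ss, genes in sorted(self.by_subsystem.items())
            for g, ts in sorted(genes.items())
            for t in sorted(ts)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class TermIC:
    """Term probabilities and information contents, per subsystem corpus."""

    p: dict[str, float]
    ic: dict[str, float]

    def __contains__(self, term: str) -> bool:
        return term in self.ic


def propagate_annotations(dag: GoDag, raw: AnnotationSet) -> AnnotationSet:
    """True-path closure: every annotation implies all ancestor terms.

    Idempotent; unknown term ids are an error listing the offenders.
    """
    unknown = sorted(
        {
            t
            for genes in raw.by_subsystem.values()
            for ts in genes.values()
            for t in ts
            if t not in dag.parents
        }
    )
    if unknown:
        raise OntologyError(f"annotations reference unknown terms: {unknown[:10]}")
    closed = {
        ss: {
            g: frozenset(set(ts) | {a for t in ts for a in dag.ancestors(t)})
            for g, ts in genes.items()
        }
        for ss, genes in raw.by_subsystem.items()
    }
    return AnnotationSet(by_subsystem=closed, propagated=True)


def information_content(dag: GoDag, annotations: AnnotationSet) -> TermIC:
    """Per-term probability and IC from propagated annotation counts.

    ``p(t)`` is the number of genes annotated to ``t`` divided by the
    number annotated to the subsystem root (so roots get p=1, IC=0).
    Terms with zero propagated annotations are excluded (logged count)
    rather than given infinite IC.
    """
    if not annotations.propagated:
        annotations = propagate_annotations(dag, annotations)
    p: dict[str, float] = {}
    ic: dict[str, float] = {}
    n_zero = 0
    for ss, genes in annotations.by_subsystem.items():
        if not genes:
            raise OntologyError(f"subsystem {ss!r} has no annotated genes")
        counts: dict[str, int] = {}
        for ts in genes.values():
            for t in ts:
                counts[t] = counts.get(t, 0) + 1
        root = dag.roots.get(ss)
        if root is None:
            raise OntologyError(f"subsystem {ss!r} has no root in the DAG")
        denom = counts.get(root, 0)
        if denom == 0:
            raise OntologyError(f"subsystem {ss!r}: no gene reaches the root")
        for t in dag.parents:
            if dag.subsystem[t] != ss:
                continue
            c = counts.get(t, 0)
            if c == 0:
                n_zero += 1
                continue
            p[t] = c / denom
            ic[t] = float(-np.log(p[t]))
    if n_zero:
        logger.info("IC: %d terms with zero annotations excluded", n_zero)
    return TermIC(p=p, ic=ic)


def minimum_subsumer(
    dag: GoDag, ic: TermIC, t1: str, t2: str
) -> tuple[str, float]:
    """Common ancestor of maximal IC (the Resnik similarity, in nats).

    The terms themselves count as their own ancestors, ties are broken by
    term id, and terms without IC (never annotated) are skipped.
    """
    if dag.subsystem.get(t1) != dag.subsystem.get(t2):
        raise OntologyError(f"terms {t1!r}, {t2!r} are in different subsystems")
    common = (dag.ancestors(t1) | {t1}) & (dag.ancestors(t2) | {t2})
    candidates = [t for t in common if t in ic]
    if not candidates:
        raise OntologyError(f"terms {t1!r}, {t2!r} share no annotated ancestor")
    best = min(candidates, key=lambda t: (-ic.ic[t], t))
    return best, ic.ic[best]


def lin_similarity(ic: TermIC, t1: str, t2: str, ic_ms: float) -> float:
    """Lin similarity: 2*IC_ms / (IC(t1)+IC(t2)); 0 when both ICs are 0."""
    denom = ic.ic[t1] + ic.ic[t2]
    if denom == 0:
        return 0.0
    return 2.0 * ic_ms / denom


class SemanticSimilarity:
    """Gene-pair semantic similarity with term-level caching.

    Term-level Lin values are memoised, which makes repeated gene-pair
    and random-control evaluations on small ontologies cheap.
    """

    def __init__(
        self,
        dag: GoDag,
        ic: TermIC,
        raw_annotations: AnnotationSet,
        combine: str = "max",
    ) -> None:
        if combine not in COMBINE_RULES:
            raise ValueError(f"combine must be one of {COMBINE_RULES}")
        if raw_annotations.propagated:
            raise ValueError(
                "gene-level similarity uses direct (pre-closure) annotations"
            )
        self.dag = dag
        self.ic = ic
        self.annotations = raw_annotations
        self.combine = combine
        self._term_cache: dict[tuple[str, str], float] = {}

    def term_sim(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        cached = self._term_cache.get(key)
        if cached is None:
            _, ic_ms = minimum_subsumer(self.dag, self.ic, t1, t2)
            cached = lin_similarity(self.ic, t1, t2, ic_ms)
            self._term_cache[key] = cached
        return cached

    def gene_pair(self, g1: str, g2: str, subsystem: str) -> float | None:
        """Combine term-level Lin over the two genes' direct annotations.

        Undefined (None) when either gene lacks usable annotation in the
        subsystem.
        """
        ts1 = [t for t in self.annotations.terms_of(g1, subsystem) if t in self.ic]
        ts2 = [t for t in self.annotations.terms_of(g2, subsystem) if t in self.ic]
        if not ts1 or not ts2:
            return None
        M = np.array([[self.term_sim(a, b) for b in ts2] for a in ts1])
        if self.combine == "max":
            return float(M.max())
        if self.combine == "mean":
            return float(M.mean())
        return float((M.max(axis=1).mean() + M.max(axis=0).mean()) / 2.0)

    def representative(self, g1: str, g2: str) -> float | None:
        vals = {ss: self.gene_pair(g1, g2, ss) for ss in self.annotations.by_subsystem}
        return representative_similarity(vals)


def gene_pair_similarity(
    dag: GoDag,
    ic: TermIC,
    annotations: AnnotationSet,
    g1: str,
    g2: str,
    subsystem: str,
    combine: str = "max",
) -> float | None:
    """Functional similarity of two genes in one subsystem (None = undefined)."""
    return SemanticSimilarity(dag, ic, annotations, combine).gene_pair(g1, g2, subsystem)


def representative_similarity(values: Mapping[str, float | None]) -> float | None:
    """Max over the defined per-subsystem similarities (None if all undefined)."""
    defined = [v for v in values.values() if v is not None]
    return max(defined) if defined else None


def funcsim_by_coexpression_threshold(
    pairs: Iterable[tuple[str, str]],
    funcsim: Mapping[tuple[str, str], float | None],
    pcc: Mapping[tuple[str, str], float],
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Mean representative similarity of pairs above each PCC threshold."""
    thresholds = list(thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted ascending")
    pairs = [
        p for p in pairs
        if p in pcc and funcsim.get(p) is not None and np.isfinite(pcc[p])
    ]
    rows = []
    for tau in thresholds:
        sel = [funcsim[p] for p in pairs if pcc[p] > tau]
        rows.append(
            {
                "threshold": tau,
                "n_pairs": len(sel),
                "mean_similarity": float(np.mean(sel)) if sel else float("nan"),
                "empty": not sel,
            }
        )
    return pd.DataFrame(rows)


def random_funcsim_control(
    engine: SemanticSimilarity,
    n_pairs: int,
    n_iter: int,
    seed: int,
) -> np.ndarray:
    """Null distribution of mean similarity over random annotated gene pairs.

    Each of the ``n_iter`` iterations samples ``n_pairs`` random pairs of
    annotated genes and records the mean representative similarity
    (pairs undefined in every subsystem are skipped within an iteration).
    Seeded and reproducible.
    """
    genes = sorted(
        {g for genes in engine.annotations.by_subsystem.values() for g in genes}
    )
    if len(genes) < 4:
        raise ValueError("need >= 4 annotated genes for a random control")
    rng = np.random.default_rng(seed)
    means = np.empty(n_iter)
    for it in range(n_iter):
        vals: list[float] = []
        attempts = 0
        while len(vals) < n_pairs:
            attempts += 1
            if attempts > 1000 * n_pairs:
                raise ValueError("too few gene pairs with defined similarity")
            i, j = rng.integers(0, len(genes), size=2)
            if i == j:
                continue
            v = engine.representative(genes[i], genes[j])
            if v is not None:
                vals.append(v)
        means[it] = float(np.mean(vals))
    return means
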