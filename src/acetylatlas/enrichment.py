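"""Ontology handling and per-tissue GO enrichment with term selection.

Annotations are propagated upward through the is-a hierarchy (a protein
annotated to a term counts for every ancestor of that term), per-tissue
enrichment of acetyl proteins against a background universe is tested with
Fisher's exact test, and heatmap terms are chosen by an across-tissue
variance criterion followed by two pruning passes (high-overlap removal
and parent-child specificity), plus a per-tissue Z-score uniqueness
ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .quantify import DetectionPattern

logger = logging.getLogger(__name__)


class CycleError(ValueError):
    """The supposed is-a DAG contains a cycle."""


@dataclass
class OntologyDAG:
    """Directed acyclic is-a hierarchy, edges child -> parent."""

    parents: dict[str, set[str]]
    _ancestors: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    @property
    def terms(self) -> set[str]:
        out = set(self.parents)
        for ps in self.parents.values():
            out |= ps
        return out

    def ancestors(self, term: str) -> frozenset[str]:
        """All strict ancestors of ``term``, memoized; raises on cycles."""
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        path: set[str] = set()

        def visit(t: str) -> frozenset[str]:
            if t in self._ancestors:
                return self._ancestors[t]
            if t in path:
                raise CycleError(f"cycle through is-a edge at term {t!r}")
            path.add(t)
            anc: set[str] = set()
            for p in self.parents.get(t, ()):  # edges child -> parent
                if p == t:
                    raise CycleError(f"self-loop is-a edge {t!r} -> {t!r}")
                anc.add(p)
                anc |= visit(p)
            path.discard(t)
            self._ancestors[t] = frozenset(anc)
            return self._ancestors[t]

        return visit(term)

    def is_ancestor(self, a: str, b: str) -> bool:
        """True iff ``a`` is a strict ancestor of ``b``."""
        return a in self.ancestors(b)


def read_edge_list(path: str | Path) -> OntologyDAG:
    """Two-column tab-separated child -> parent edge list."""
    parents: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            child, parent = line.split("\t")[:2]
            parents.setdefault(child, set()).add(parent)
    return OntologyDAG(parents)


def read_obo(path: str | Path) -> OntologyDAG:
    """Read is-a edges from an OBO ontology file."""
    import obonet

    graph = obonet.read_obo(str(path))
    parents: dict[str, set[str]] = {}
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents.setdefault(child, set()).add(parent)
    return OntologyDAG(parents)


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Two-column tab-separated protein -> term table into direct term sets."""
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            protein, term = line.split("\t")[:2]
            direct.setdefault(protein, set()).add(term)
    return direct


def ancestor_closure(
    dag: OntologyDAG, direct: dict[str, set[str]]
) -> dict[str, set[str]]:
    """Close each protein's term set upward through the hierarchy."""
    closed: dict[str, set[str]] = {}
    for protein, terms in direct.items():
        full = set(terms)
        for t in terms:
            full |= dag.ancestors(t)
        closed[protein] = full
    return closed


def fisher_exact_2x2(table, alternative: str = "greater") -> float:
    """Fisher's exact test p-value for a 2x2 count table.

    One-sided (greater) by default: the over-representation direction.
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    return float(stats.fisher_exact(arr, alternative=alternative).pvalue)


@dataclass
class EnrichmentMatrix:
    """Term x tissue Fisher p-values with -log10 summaries."""

    pvalues: pd.DataFrame          # term x tissue, in (0, 1]
    sd_ddof: int = 1

    @property
    def neglog10(self) -> pd.DataFrame:
        return -np.log10(self.pvalues)

    @property
    def term_mean(self) -> pd.Series:
        return self.neglog10.mean(axis=1)

    @property
    def term_sd(self) -> pd.Series:
        return self.neglog10.std(axis=1, ddof=self.sd_ddof)


def tissue_enrichment(
    detection: DetectionPattern,
    site_proteins: dict[str, str],
    annotations: dict[str, set[str]],
    universe: set[str],
    cfg: PipelineConfig | None = None,
) -> EnrichmentMatrix:
    """Per-tissue GO enrichment of acetyl proteins against the universe.

    For each tissue, the acetyl set is the proteins carrying a detected
    site there.  Each (term, tissue) cell tests annotated-vs-not against
    in-tissue vs rest-of-universe counts; tissues with no acetyl proteins
    get p = 1.0 in every term (test not computable).
    """
    cfg = cfg or PipelineConfig()
    if not universe:
        raise ValueError("empty background universe")
    terms = sorted(set().union(
        *(annotations.get(p, set()) for p in universe)
    ) if universe else set())
    annotated = {
        t: {p for p in universe if t in annotations.get(p, set())} for t in terms
    }
    tissues = list(detection.detected.columns)
    pvals = pd.DataFrame(1.0, index=pd.Index(terms, name="term"), columns=tissues)
    n_universe = len(universe)
    for tissue in tissues:
        col = detection.detected[tissue]
        acetyl = {
            site_proteins[k] for k in col.index[col] if site_proteins[k] in universe
        }
        if not acetyl:
            logger.info("tissue %s: no acetyl proteins; p = 1.0 throughout", tissue)
            continue
        m = len(acetyl)
        for t in terms:
            a = len(annotated[t] & acetyl)
            b = m - a
            c = len(annotated[t]) - a
            d = (n_universe - m) - c
            pvals.at[t, tissue] = fisher_exact_2x2(
                [[a, b], [c, d]], alternative=cfg.ora_alternative
            )
    return EnrichmentMatrix(pvals, sd_ddof=cfg.sd_ddof)


def select_variable_terms(
    em: EnrichmentMatrix, cfg: PipelineConfig | None = None
) -> list[str]:
    """Keep terms with tissue-variable enrichment.

    A term survives only if, across tissues, its -log10 p values have
    sd strictly above ``term_sd_min``, some tissue strictly below
    ``term_low_max``, and some tissue strictly above ``term_high_min``.
    """
    cfg = cfg or PipelineConfig()
    nl = em.neglog10
    sd = nl.std(axis=1, ddof=cfg.sd_ddof)
    keep = (
        (sd > cfg.term_sd_min)
        & (nl.min(axis=1) < cfg.term_low_max)
        & (nl.max(axis=1) > cfg.term_high_min)
    )
    return sorted(nl.index[keep])


def prune_overlapping_terms(
    terms: list[str],
    term_proteins: dict[str, set[str]],
    em: EnrichmentMatrix | None = None,
    cfg: PipelineConfig | None = None,
) -> list[str]:
    """Drop one member of every pair overlapping more than ``overlap_max``.

    Overlap is |A∩B| / min(|A|,|B|) over the terms' annotated protein
    sets; exactly 90% keeps both (strictly "more than").  The member with
    the larger maximum -log10 p survives (ties: lexicographically smaller
    id), so the most informative term is kept deterministically.
    """
    cfg = cfg or PipelineConfig()
    score = (
        em.neglog10.max(axis=1) if em is not None
        else pd.Series(0.0, index=pd.Index(terms))
    )
    # keep-priority: stronger term first, then id
    ordered = sorted(terms, key=lambda t: (-float(score.get(t, 0.0)), t))
    kept: list[str] = []
    for t in ordered:
        s_t = term_proteins.get(t, set())
        ok = True
        for other in kept:
            s_o = term_proteins.get(other, set())
            denom = min(len(s_t), len(s_o))
            if denom == 0:
                continue
            if len(s_t & s_o) / denom > cfg.overlap_max:
                ok = False
                break
        if ok:
            kept.append(t)
    return sorted(kept)


def prune_parent_child(terms: list[str], dag: OntologyDAG) -> list[str]:
    """Keep only the most specific term of every ancestor-descendant pair."""
    term_set = set(terms)
    kept = [
        t for t in terms
        if not any(dag.is_ancestor(t, other) for other in term_set if other != t)
    ]
    return sorted(kept)


def rank_unique_terms(
    em: EnrichmentMatrix,
    tissue: str,
    cfg: PipelineConfig | None = None,
    terms: list[str] | None = None,
) -> pd.Series:
    """Terms most uniquely enriched in one tissue.

    Each term's -log10 p vector is Z-scored across tissues; terms are
    ranked by the gap between the target tissue's Z and the mean Z of the
    other tissues, descending.  Terms constant across tissues score 0.
    Returns the top ``top_k_unique`` scores.
    """
    cfg = cfg or PipelineConfig()
    nl = em.neglog10 if terms is None else em.neglog10.loc[terms]
    if nl.shape[1] < 2:
        raise ValueError("uniqueness ranking requires at least 2 tissues")
    mean = nl.mean(axis=1)
    sd = nl.std(axis=1, ddof=cfg.sd_ddof)
    z = nl.sub(mean, axis=0).div(sd.where(sd > 0, np.inf), axis=0)
    others = [c for c in nl.columns if c != tissue]
    score = z[tissue] - z[others].mean(axis=1)
    return score.sort_values(ascending=False, kind="stable").head(cfg.top_k_unique)
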