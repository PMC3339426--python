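"""GO-term enrichment of probe sets with true-path propagation.

An entity annotated to a GO term is implicitly annotated to every
ancestor of that term (the true-path rule), so annotations are first
propagated up the DAG along is_a/part_of edges.  Each term is then
tested for over-representation in a selected probe set against a probe
universe with the one-sided hypergeometric upper tail, followed by
multiple-testing adjustment (Benjamini-Yekutieli by default, since the
tests along a DAG are strongly dependent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from xhyb.de import fdr_adjust
from xhyb.io import AnnotationTable, GoDag


@dataclass
class PropagatedAnnotation:
    """Term -> entity sets after true-path propagation up the DAG."""
    entities_of: dict[str, set[str]]
    namespaces: dict[str, str]

    def annotated_entities(self) -> set[str]:
        out: set[str] = set()
        for ents in self.entities_of.values():
            out |= ents
        return out

    def counts(self) -> dict[str, int]:
        return {t: len(e) for t, e in self.entities_of.items()}


def propagate(dag: GoDag, direct: AnnotationTable) -> PropagatedAnnotation:
    """Propagate direct annotations to all ancestor terms (set semantics:
    an entity reachable through several paths is counted once)."""
    unknown = sorted({t for _, terms in direct.items() for t in terms
                      if t not in dag})
    if unknown:
        raise KeyError(f"annotation uses unknown term id(s): {unknown[:10]}")
    entities_of: dict[str, set[str]] = {}
    for entity, terms in direct.items():
        reached: set[str] = set()
        for term in terms:
            reached.add(term)
            reached |= dag.ancestors(term)
        for term in reached:
            entities_of.setdefault(term, set()).add(entity)
    return PropagatedAnnotation(entities_of, dict(dag.namespaces))


def enrich(selected: set[str], universe: set[str],
           ann: PropagatedAnnotation,
           adjust: str = "by",
           by_namespace: bool = True) -> pd.DataFrame:
    """Hypergeometric enrichment of ``selected`` within ``universe``.

    Per term with k = |selected & annotated| > 0:
    p = P(X >= k) for X ~ Hypergeom(N=|universe|, K=|universe & annotated|,
    n=|selected|).  Adjustment runs within each GO namespace when
    ``by_namespace`` (mirroring tools that test BP/MF/CC separately).
    Results are sorted by p with term-id tie-break.
    """
    extra = selected - universe
    if extra:
        raise ValueError(
            f"selected probes outside the universe: {sorted(extra)[:5]}")
    N, n = len(universe), len(selected)
    rows = []
    for term in sorted(ann.entities_of):
        annotated = ann.entities_of[term] & universe
        K = len(annotated)
        k = len(annotated & selected)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        ratio = (k / n) / (K / N) if n and K else np.nan
        rows.append({
            "term": term, "namespace": ann.namespaces.get(term, "unknown"),
            "k": k, "K": K, "n": n, "N": N,
            "enrichment_ratio": ratio, "p": p})
    df = pd.DataFrame(rows, columns=["term", "namespace", "k", "K", "n", "N",
                                     "enrichment_ratio", "p"])
    if df.empty:
        df["q"] = pd.Series(dtype=float)
        return df
    method = {"by": "by", "bh": "bh"}.get(adjust)
    if adjust == "bonferroni":
        df["q"] = np.minimum(df["p"] * len(df), 1.0)
    elif method is not None:
        if by_namespace:
            df["q"] = np.nan
            for _, idx in df.groupby("namespace").groups.items():
                df.loc[idx, "q"] = fdr_adjust(
                    df.loc[idx, "p"].to_numpy(), method=method)
        else:
            df["q"] = fdr_adjust(df["p"].to_numpy(), method=method)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    df = df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    return df


def annotation_universe(ann: PropagatedAnnotation) -> set[str]:
    """Default universe: all entities carrying >= 1 propagated term."""
    return ann.annotated_entities()


def enriched_subgraph_dot(dag: GoDag, result: pd.DataFrame,
                          q_cutoff: float = 0.05) -> str:
    """DOT text of the enriched terms and their DAG relations."""
    enriched = set(result.loc[result["q"] <= q_cutoff, "term"])
    lines = ["digraph enrichment {"]
    for term in sorted(enriched):
        label = dag.names.get(term, term).replace('"', "'")
        lines.append(f'  "{term}" [label="{term}\\n{label}" '
                     f'style=filled fillcolor=yellow];')
    for term in sorted(enriched):
        for parent in sorted(dag.parents(term)):
            if parent in enriched:
                lines.append(f'  "{term}" -> "{parent}" [color=red];')
    lines.append("}")
    return "\n".join(lines)
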