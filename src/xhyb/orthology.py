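"""EST translation, ortholog clustering and annotation projection.

ESTs from species without an annotated genome carry little functional
annotation of their own.  This module translates ESTs to their best
protein (six-frame longest ORF), clusters the translations together with
annotated reference proteomes into orthologous groups by Markov
clustering of a similarity graph, and projects GO/InterPro terms from
annotated cluster members onto the unannotated ones — and from there,
through the hybridization graph, onto array probes.

The translator is a deterministic six-frame longest-ORF caller; the
clustering is e-value-derived symmetric similarity followed by Markov
clustering (expansion power 2, configurable inflation).  Both accept
externally produced results (protein FASTA, cluster files) as
alternative inputs, so richer external tools can be slotted in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from xhyb.io import AnnotationTable, SequenceSet
from xhyb.hybgraph import HybGraph

logger = logging.getLogger(__name__)

MCL_EXPANSION = 2
MCL_MAX_ITER = 100
MCL_TOL = 1e-6
MCL_PRUNE = 1e-8
SIMILARITY_CEILING = 200.0   # cap on -log10(evalue); evalue 0 maps here


@dataclass
class ProteinSet:
    """Best protein translation per EST with its reading frame."""
    records: list[tuple[str, str, str, str, int]]
    # (protein_id, source_est_id, species, sequence, frame in {+-1,+-2,+-3})

    def __len__(self):
        return len(self.records)

    @property
    def est_to_protein(self) -> dict[str, str]:
        return {est: pid for pid, est, _, _, _ in self.records}

    def to_sequence_set(self) -> SequenceSet:
        return SequenceSet(
            [(pid, f"{est} frame={frame:+d}", seq)
             for pid, est, _, seq, frame in self.records],
            alphabet="protein")


@dataclass
class OrthoClusterSet:
    """A partition of proteins into orthologous clusters."""
    clusters: dict[str, set[str]]
    species_of: dict[str, str] = field(default_factory=dict)
    inflation: float = 1.5

    def __len__(self):
        return len(self.clusters)

    def cluster_of(self, member: str) -> str:
        for cid, members in self.clusters.items():
            if member in members:
                return cid
        raise KeyError(member)

    def members(self) -> set[str]:
        out: set[str] = set()
        for m in self.clusters.values():
            out |= m
        return out


@dataclass
class ProjectedAnnotation:
    """Annotation table plus per-term provenance (source species/gene)."""
    table: AnnotationTable
    provenance: dict[str, dict[str, set[tuple[str, str]]]] = field(
        default_factory=dict)
    # entity -> term -> {(source_species, source_gene)}


# ---------------------------------------------------------------------------
# Translation

_FRAMES = (1, 2, 3, -1, -2, -3)


def _orfs_in_frame(nt: str) -> list[tuple[int, str]]:
    """ATG-to-stop ORFs in one forward frame of an in-frame sequence."""
    peptide = str(Seq(nt[:len(nt) - len(nt) % 3]).translate())
    orfs = []
    start = None
    for i, aa in enumerate(peptide):
        if aa == "M" and start is None:
            start = i
        elif aa == "*" and start is not None:
            orfs.append((start, peptide[start:i]))
            start = None
    if start is not None:
        orfs.append((start, peptide[start:]))
    return orfs


def _stop_free_stretches(nt: str) -> list[tuple[int, str]]:
    peptide = str(Seq(nt[:len(nt) - len(nt) % 3]).translate())
    out, start = [], 0
    for i, aa in enumerate(peptide):
        if aa == "*":
            if i > start:
                out.append((start, peptide[start:i]))
            start = i + 1
    if len(peptide) > start:
        out.append((start, peptide[start:]))
    return out


def translate_ests(ests: SequenceSet, min_orf_aa: int = 30,
                   species: str = "unknown") -> ProteinSet:
    """Six-frame longest-ORF translation of each EST.

    The longest ATG-to-stop ORF of length >= ``min_orf_aa`` across all six
    frames wins; if none qualifies, the longest stop-free stretch is used
    instead (still subject to the length floor).  Ties break to the lowest
    frame number (+1,+2,+3,-1,-2,-3 order), then to the leftmost start.
    ESTs with no qualifying ORF are omitted and logged.
    """
    if ests.alphabet != "nucleotide":
        raise ValueError("translate_ests requires nucleotide input")
    records = []
    skipped = []
    for est_id, _, seq in ests.records:
        seq = seq.upper().replace("U", "T")
        rc = str(Seq(seq).reverse_complement())
        candidates = []  # (length, frame_rank, start, frame, peptide)
        for rank, frame in enumerate(_FRAMES):
            sub = (seq[frame - 1:] if frame > 0 else rc[-frame - 1:])
            for finder in (_orfs_in_frame, _stop_free_stretches):
                for start, pep in finder(sub):
                    if len(pep) >= min_orf_aa:
                        # ATG ORFs rank before stop-free fallbacks
                        is_fallback = finder is _stop_free_stretches
                        candidates.append(
                            (is_fallback, -len(pep), rank, start, frame, pep))
        if not candidates:
            skipped.append(est_id)
            continue
        candidates.sort()
        _, _, _, _, frame, pep = candidates[0]
        records.append((f"{est_id}_p", est_id, species, pep, frame))
    if skipped:
        logger.info("translate_ests: %d EST(s) with no ORF >= %d aa: %s%s",
                    len(skipped), min_orf_aa, ",".join(skipped[:5]),
                    "..." if len(skipped) > 5 else "")
    return ProteinSet(records)


# ---------------------------------------------------------------------------
# Markov clustering of the protein similarity graph

def _mcl(matrix: np.ndarray, inflation: float) -> list[set[int]]:
    """Markov clustering on a dense similarity matrix; returns index sets."""
    n = matrix.shape[0]
    m = matrix.astype(float).copy()
    np.fill_diagonal(m, np.maximum(m.diagonal(), m.max(axis=0)))
    colsum = m.sum(axis=0)
    colsum[colsum == 0] = 1.0
    m = m / colsum
    for _ in range(MCL_MAX_ITER):
        prev = m
        m = np.linalg.matrix_power(m, MCL_EXPANSION)
        m = np.power(m, inflation)
        m[m < MCL_PRUNE] = 0.0
        colsum = m.sum(axis=0)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if np.max(np.abs(m - prev)) < MCL_TOL:
            break
    # attractor-based extraction: connected components of the support graph
    support = (m + m.T) > 0
    np.fill_diagonal(support, True)
    seen = np.zeros(n, dtype=bool)
    clusters = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], set()
        while stack:
            j = stack.pop()
            if seen[j]:
                continue
            seen[j] = True
            comp.add(j)
            stack.extend(np.nonzero(support[j])[0].tolist())
        clusters.append(comp)
    return clusters


def cluster_orthologs(protein_hits: pd.DataFrame,
                      inflation: float = 1.5,
                      evalue_cutoff: float = 1e-5,
                      species_of: dict[str, str] | None = None,
                      all_proteins: set[str] | None = None) -> OrthoClusterSet:
    """Cluster proteins into orthologous groups from all-vs-all hits.

    Similarity s(i,j) = -log10(evalue), capped at
    :data:`SIMILARITY_CEILING` and symmetrized by max; hits with e-value
    above ``evalue_cutoff`` are discarded.  Markov clustering of the
    resulting graph yields the partition; proteins with no retained hit
    (including any in ``all_proteins`` absent from the table) become
    singleton clusters.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    hits = protein_hits[protein_hits["evalue"] <= evalue_cutoff]
    ids = sorted(set(hits["query_id"]) | set(hits["subject_id"])
                 | set(all_proteins or ()))
    index = {pid: i for i, pid in enumerate(ids)}
    n = len(ids)
    sim = np.zeros((n, n))
    with np.errstate(divide="ignore"):
        scores = np.minimum(-np.log10(hits["evalue"].to_numpy()),
                            SIMILARITY_CEILING)
    for (q, s), score in zip(
            zip(hits["query_id"], hits["subject_id"]), scores):
        i, j = index[q], index[s]
        if i == j:
            continue
        val = max(sim[i, j], score)
        sim[i, j] = sim[j, i] = val
    clusters = {}
    for k, comp in enumerate(sorted(_mcl(sim, inflation),
                                    key=lambda c: ids[min(c)])):
        clusters[f"CL{k + 1:05d}"] = {ids[i] for i in comp}
    return OrthoClusterSet(clusters, species_of=dict(species_of or {}),
                           inflation=inflation)


def read_clusters(path) -> OrthoClusterSet:
    """Read a precomputed cluster file: ``cluster_id<TAB>m1,m2,...``."""
    clusters = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            cid, _, members = line.partition("\t")
            clusters[cid] = set(members.split(","))
    return OrthoClusterSet(clusters)


def write_clusters(cs: OrthoClusterSet, path) -> None:
    with open(path, "w") as fh:
        for cid in sorted(cs.clusters):
            fh.write(f"{cid}\t{','.join(sorted(cs.clusters[cid]))}\n")


# ---------------------------------------------------------------------------
# Annotation projection

def project_annotations(clusters: OrthoClusterSet,
                        reference_annotations: AnnotationTable
                        ) -> ProjectedAnnotation:
    """Project reference annotations onto all members of each cluster.

    Every member receives the union of the terms of all annotated members
    of its cluster (accumulation, not voting), with provenance recording
    which source species/gene contributed each term.  Members of singleton
    clusters with no annotated partner receive the empty set.
    """
    table: dict[str, set[str]] = {}
    provenance: dict[str, dict[str, set[tuple[str, str]]]] = {}
    for members in clusters.clusters.values():
        sources = [(m, reference_annotations[m]) for m in members
                   if m in reference_annotations
                   and reference_annotations[m]]
        union: set[str] = set()
        for _, terms in sources:
            union |= terms
        for m in members:
            table[m] = set(union)
            prov = provenance.setdefault(m, {})
            for src, terms in sources:
                sp = clusters.species_of.get(src, "unknown")
                for t in terms:
                    prov.setdefault(t, set()).add((sp, src))
    return ProjectedAnnotation(AnnotationTable(table), provenance)


def annotate_probes(graph: HybGraph,
                    est_annotations: ProjectedAnnotation | AnnotationTable,
                    est_to_protein: dict[str, str] | None = None
                    ) -> AnnotationTable:
    """Transfer EST annotations to probes through the hybridization graph.

    probe annotation = union over transcripts adjacent to the probe;
    isolated probes get (and keep) the empty set.  ``est_to_protein``
    links transcript ids to translated protein ids when the annotation is
    keyed by protein.
    """
    if isinstance(est_annotations, ProjectedAnnotation):
        ann = est_annotations.table
    else:
        ann = est_annotations
    est_to_protein = est_to_protein or {}
    out: dict[str, set[str]] = {}
    for probe in graph.probes:
        terms: set[str] = set()
        for transcript in graph.neighbors(probe):
            key = est_to_protein.get(transcript, transcript)
            if key in ann:
                terms |= ann[key]
        out[probe] = terms
    return AnnotationTable(out)
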