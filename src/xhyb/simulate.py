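"""Seeded generators for every input the workflow consumes.

Each generator is a pure function of (parameters, seed) and returns the
fixture together with its planted ground truth, so every stage of the
pipeline can be tested end to end without external data.

The array generator emulates the study design it is meant to exercise:
three two-color slides comparing two transgenic lines against wild type
— a dye-swapped pair for the first line and a single slide for the
second — with within-array duplicate spots, log-normal signal, additive
normal background, an intensity-dependent dye bias that is a smooth
function of A, and correlated duplicate-spot noise.  What it does not
emulate: spatial artifacts, saturation, or sequence-driven
cross-hybridization intensity effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from xhyb.io import (AnnotationTable, GoDag, SequenceSet, TwoColorArray)
import networkx as nx

NUCLEOTIDES = np.array(list("ACGT"))

# study-design defaults: 3 slides (dye-swapped pair for line 37, one
# slide for line 45), duplicate-spotted probes, |log2 FC| 1.5 for
# planted differential probes
PAPER_DESIGN = (
    ("array_37A", "line37", "treatment_in_ch1"),
    ("array_37B", "line37", "treatment_in_ch2"),
    ("array_45A", "line45", "treatment_in_ch1"),
)
DEFAULT_EFFECT_LOG2 = 1.5
DEFAULT_DUP_CORRELATION = 0.7
SPOT_NOISE_SD = 0.2          # log2-scale technical noise per channel
BACKGROUND_MEAN = 100.0
BACKGROUND_SD = 10.0
FLAG_BAD_FRACTION = 0.02
N_PRINT_TIP_BLOCKS = 8
FRACTION_DOWN = 0.75         # most planted effects are down-regulation


@dataclass
class FixtureTruth:
    """Planted ground truth serialized alongside each fixture."""
    seed: int
    params: dict = field(default_factory=dict)
    true_edges: list[tuple[str, str]] | None = None
    true_partition: list[list[str]] | None = None
    de_probes: dict[str, dict[str, float]] | None = None
    enriched_term: str | None = None
    modules: list[list[str]] | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)


def _random_seqs(rng, prefix: str, n: int, length: int) -> SequenceSet:
    recs = []
    for i in range(n):
        seq = "".join(rng.choice(NUCLEOTIDES, size=length))
        recs.append((f"{prefix}{i + 1:05d}", "", seq))
    return SequenceSet(recs, alphabet="nucleotide")


# ---------------------------------------------------------------------------
# hybridization-graph fixture

def make_hybridization_fixture(n_probes: int = 300, n_transcripts: int = 400,
                               edge_density: float = 1.2,
                               identity_range: tuple[float, float] = (85.0, 99.0),
                               seed: int = 0):
    """Probe/transcript sequences plus a hit table with planted edges.

    ``edge_density`` is the mean number of qualifying transcripts per
    probe (Poisson).  Planted edges have identity/length above the
    (80 %, 100 bp) thresholds; each probe also gets decoy hits below
    threshold.  Filtering the table at the defaults recovers exactly the
    planted edges.

    Returns (probe SequenceSet, transcript SequenceSet, hit DataFrame,
    FixtureTruth).
    """
    rng = np.random.default_rng(seed)
    probes = _random_seqs(rng, "PRB", n_probes, 400)
    transcripts = _random_seqs(rng, "EST", n_transcripts, 600)
    tids = transcripts.ids
    rows, true_edges = [], []
    for pid in probes.ids:
        k = rng.poisson(edge_density)
        targets = rng.choice(tids, size=min(k, n_transcripts), replace=False)
        for tid in targets:
            ident = rng.uniform(*identity_range)
            length = int(rng.integers(120, 500))
            rows.append((tid, pid, round(ident, 1), length,
                         10.0 ** -rng.uniform(20, 80),
                         round(2 * length * ident / 100, 1)))
            true_edges.append((pid, tid))
        # decoys: below identity or length cutoff
        for _ in range(int(rng.integers(1, 4))):
            tid = tids[int(rng.integers(n_transcripts))]
            if rng.random() < 0.5:
                ident, length = rng.uniform(50, 79.5), int(rng.integers(120, 400))
            else:
                ident, length = rng.uniform(81, 95), int(rng.integers(30, 99))
            rows.append((tid, pid, round(ident, 1), length,
                         10.0 ** -rng.uniform(2, 10),
                         round(length * ident / 100, 1)))
    hits = pd.DataFrame(rows, columns=[
        "query_id", "subject_id", "percent_identity", "alignment_length",
        "evalue", "bitscore"])
    truth = FixtureTruth(
        seed=seed,
        params={"n_probes": n_probes, "n_transcripts": n_transcripts,
                "edge_density": edge_density,
                "identity_range": list(identity_range)},
        true_edges=sorted(set(true_edges)))
    return probes, transcripts, hits, truth


def make_gene_count_fixture(n_probes: int = 318, n_genes: int = 250,
                            seed: int = 0):
    """Wire ``n_probes`` probes into exactly ``n_genes`` components.

    Each component gets one transcript; extra probes beyond one per
    component are attached round-robin, so probes sharing a transcript
    collapse into the same component (several probes, one gene).
    Returns (hit DataFrame, probe ids, FixtureTruth).
    """
    if n_genes > n_probes:
        raise ValueError("cannot have more genes than probes")
    rng = np.random.default_rng(seed)
    probe_ids = [f"PRB{i + 1:05d}" for i in range(n_probes)]
    transcript_ids = [f"EST{i + 1:05d}" for i in range(n_genes)]
    assignment = list(range(n_genes))
    extra = [int(i % n_genes) for i in range(n_probes - n_genes)]
    assignment += extra
    rows = []
    partition: dict[int, list[str]] = {}
    for pid, gene in zip(probe_ids, assignment):
        ident = float(rng.uniform(85, 99))
        length = int(rng.integers(120, 500))
        rows.append((transcript_ids[gene], pid, round(ident, 1), length,
                     1e-30, round(2 * length, 1)))
        partition.setdefault(gene, []).append(pid)
    hits = pd.DataFrame(rows, columns=[
        "query_id", "subject_id", "percent_identity", "alignment_length",
        "evalue", "bitscore"])
    truth = FixtureTruth(
        seed=seed, params={"n_probes": n_probes, "n_genes": n_genes},
        true_partition=[sorted(v) for v in partition.values()])
    return hits, probe_ids, truth


# ---------------------------------------------------------------------------
# ortholog-clustering fixture

def make_ortholog_fixture(n_clusters: int = 10, cluster_size: int = 5,
                          within_logE: float = 50.0, between_rate: float = 0.02,
                          n_reference_terms: int = 3, seed: int = 0):
    """All-vs-all protein hits with a planted cluster partition.

    Within-cluster pairs get strong hits (e-value ~ 1e-``within_logE``);
    between-cluster pairs get weak decoy hits (e-value near 1) at rate
    ``between_rate``.  One member per cluster is a "reference" protein
    carrying GO terms; the rest are unannotated EST translations.

    Returns (hit DataFrame, reference AnnotationTable, species map,
    FixtureTruth).
    """
    rng = np.random.default_rng(seed)
    clusters, species_of = [], {}
    annotations: dict[str, set[str]] = {}
    rows = []
    all_ids = []
    for c in range(n_clusters):
        members = []
        for m in range(cluster_size):
            if m == 0:
                pid = f"ARATH_G{c + 1:03d}"
                species_of[pid] = "arabidopsis"
                annotations[pid] = {
                    f"GO:{c * n_reference_terms + t + 1:07d}"
                    for t in range(n_reference_terms)}
            else:
                pid = f"EST_C{c + 1:03d}M{m}"
                species_of[pid] = "tobacco"
            members.append(pid)
            all_ids.append(pid)
        clusters.append(sorted(members))
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                ev = 10.0 ** -(within_logE + rng.uniform(-10, 10))
                rows.append((a, b, 90.0, 200, ev, 400.0))
    n = len(all_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < between_rate:
                rows.append((all_ids[i], all_ids[j], 40.0, 80,
                             10.0 ** -rng.uniform(0, 3), 30.0))
    hits = pd.DataFrame(rows, columns=[
        "query_id", "subject_id", "percent_identity", "alignment_length",
        "evalue", "bitscore"])
    truth = FixtureTruth(
        seed=seed,
        params={"n_clusters": n_clusters, "cluster_size": cluster_size,
                "within_logE": within_logE, "between_rate": between_rate},
        true_partition=clusters)
    return hits, AnnotationTable(annotations), species_of, truth


# ---------------------------------------------------------------------------
# two-color experiment fixture

def _dye_bias(a: np.ndarray, dye_effect: float) -> np.ndarray:
    """Smooth intensity-dependent bias added to the Cy5 (ch1) log2 signal."""
    z = (a - 10.0) / 3.0
    return dye_effect * (0.5 - 0.4 * z + 0.3 * z * z)


def make_two_color_experiment(n_probes: int = 2000,
                              design=PAPER_DESIGN,
                              n_de_shared: int = 50,
                              n_de_discordant: int = 0,
                              effect_log2: float = DEFAULT_EFFECT_LOG2,
                              dup_correlation: float = DEFAULT_DUP_CORRELATION,
                              dye_effect: float = 0.3,
                              noise_sd: float = SPOT_NOISE_SD,
                              fraction_down: float = FRACTION_DOWN,
                              seed: int = 0):
    """Simulated two-color slides with planted differential expression.

    Every probe is spotted twice per array (within-array duplicates).
    ``n_de_shared`` probes get the same signed log2 effect in both lines
    (a ``fraction_down`` share of them down-regulated);
    ``n_de_discordant`` probes get opposite signs in the two lines.

    Returns (list of TwoColorArray, targets DataFrame, FixtureTruth).
    """
    rng = np.random.default_rng(seed)
    probe_ids = [f"PRB{i + 1:05d}" for i in range(n_probes)]
    lines = sorted({line for _, line, _ in design})
    baseline = rng.uniform(7.0, 13.0, size=n_probes)

    effects = {line: np.zeros(n_probes) for line in lines}
    de_idx = rng.choice(n_probes, size=n_de_shared + n_de_discordant,
                        replace=False)
    shared_idx = de_idx[:n_de_shared]
    disc_idx = de_idx[n_de_shared:]
    n_down = int(round(fraction_down * n_de_shared))
    signs = np.array([-1.0] * n_down + [1.0] * (n_de_shared - n_down))
    de_probes: dict[str, dict[str, float]] = {}
    for i, s in zip(shared_idx, signs):
        for line in lines:
            effects[line][i] = s * effect_log2
        de_probes[probe_ids[i]] = {line: s * effect_log2 for line in lines}
    for j, i in enumerate(disc_idx):
        s = 1.0 if j % 2 == 0 else -1.0
        if len(lines) >= 2:
            effects[lines[0]][i] = s * effect_log2
            effects[lines[1]][i] = -s * effect_log2
            de_probes[probe_ids[i]] = {lines[0]: s * effect_log2,
                                       lines[1]: -s * effect_log2}

    # spot layout: duplicates interleaved, blocks assigned round-robin
    n_spots = 2 * n_probes
    spots_per_block = int(np.ceil(n_spots / N_PRINT_TIP_BLOCKS))
    n_cols = max(int(np.ceil(np.sqrt(spots_per_block))), 1)

    arrays, targets_rows = [], []
    for array_id, line, orientation in design:
        eff = effects[line]
        rows = []
        shared_t = rng.normal(0, noise_sd, n_probes)
        shared_r = rng.normal(0, noise_sd, n_probes)
        for dup in range(2):
            ind_t = rng.normal(0, noise_sd, n_probes)
            ind_r = rng.normal(0, noise_sd, n_probes)
            sq = np.sqrt(dup_correlation)
            sq1 = np.sqrt(1 - dup_correlation)
            e_t = sq * shared_t + sq1 * ind_t
            e_r = sq * shared_r + sq1 * ind_r
            l_trt = baseline + eff / 2.0 + e_t
            l_ref = baseline - eff / 2.0 + e_r
            if orientation == "treatment_in_ch1":
                l1, l2 = l_trt, l_ref
            else:
                l1, l2 = l_ref, l_trt
            a_true = 0.5 * (l1 + l2)
            l1 = l1 + _dye_bias(a_true, dye_effect)
            for i, pid in enumerate(probe_ids):
                spot = dup * n_probes + i
                block = spot % N_PRINT_TIP_BLOCKS + 1
                within = spot // N_PRINT_TIP_BLOCKS
                bg1 = max(rng.normal(BACKGROUND_MEAN, BACKGROUND_SD), 0.0)
                bg2 = max(rng.normal(BACKGROUND_MEAN, BACKGROUND_SD), 0.0)
                fg1 = 2.0 ** l1[i] + bg1 + rng.normal(0, 5)
                fg2 = 2.0 ** l2[i] + bg2 + rng.normal(0, 5)
                flag = -50 if rng.random() < FLAG_BAD_FRACTION else 0
                rows.append((pid, block, within // n_cols + 1,
                             within % n_cols + 1, max(fg1, 0.0), bg1,
                             max(fg2, 0.0), bg2, flag))
        spots = pd.DataFrame(rows, columns=[
            "probe_id", "block", "row", "column", "fg_ch1", "bg_ch1",
            "fg_ch2", "bg_ch2", "flag"])
        arrays.append(TwoColorArray(spots=spots, array_id=array_id,
                                    dye_orientation=orientation))
        targets_rows.append({"array_id": array_id, "line": line,
                             "dye_orientation": orientation})
    targets = pd.DataFrame(targets_rows)
    truth = FixtureTruth(
        seed=seed,
        params={"n_probes": n_probes, "n_de_shared": n_de_shared,
                "n_de_discordant": n_de_discordant,
                "effect_log2": effect_log2,
                "dup_correlation": dup_correlation,
                "dye_effect": dye_effect, "noise_sd": noise_sd},
        de_probes=de_probes)
    return arrays, targets, truth


def paper_design_matrix(targets: pd.DataFrame) -> pd.DataFrame:
    """0/1 design: one coefficient per line, rows indexed by array id."""
    lines = sorted(targets["line"].unique())
    design = pd.DataFrame(0.0, index=list(targets["array_id"]), columns=lines)
    for _, row in targets.iterrows():
        design.loc[row["array_id"], row["line"]] = 1.0
    return design


# ---------------------------------------------------------------------------
# GO enrichment fixture

def make_go_fixture(n_terms: int = 50, depth: int = 4, n_entities: int = 500,
                    planted_term: str | None = None,
                    fold_enrichment: float = 5.0,
                    n_selected: int = 60, background_terms: int = 2,
                    seed: int = 0):
    """Random GO-like DAG, annotations and a selected set with one
    planted over-represented term.

    Entities annotated (directly) to the planted term enter the selected
    set with ``fold_enrichment`` times the weight of other entities;
    fold 1 gives a null selection.

    Returns (GoDag, AnnotationTable, selected set, FixtureTruth).
    """
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    root = terms[0]
    levels: list[list[str]] = [[root]]
    remaining = terms[1:]
    per_level = max(1, len(remaining) // max(depth, 1))
    for d in range(depth):
        chunk = (remaining[d * per_level:(d + 1) * per_level]
                 if d < depth - 1 else remaining[d * per_level:])
        if chunk:
            levels.append(chunk)
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    for d in range(1, len(levels)):
        for t in levels[d]:
            parent = levels[d - 1][int(rng.integers(len(levels[d - 1])))]
            g.add_edge(t, parent, relation="is_a")
            if d > 1 and rng.random() < 0.2:
                extra = levels[d - 1][int(rng.integers(len(levels[d - 1])))]
                if extra != parent:
                    g.add_edge(t, extra, relation="part_of")
    dag = GoDag(g, {t: f"term {t}" for t in terms},
                {t: "biological_process" for t in terms})
    annotatable = [t for t in terms if t != root]
    if planted_term is None:
        planted_term = levels[-1][0]
    ann: dict[str, set[str]] = {}
    entity_ids = [f"PRB{i + 1:05d}" for i in range(n_entities)]
    for eid in entity_ids:
        k = int(rng.integers(1, background_terms + 2))
        ann[eid] = set(rng.choice(annotatable, size=min(k, len(annotatable)),
                                  replace=False))
    carriers = [e for e in entity_ids if planted_term in ann[e]]
    others = [e for e in entity_ids if planted_term not in ann[e]]
    n_selected = min(n_selected, n_entities)
    prevalence = len(carriers) / n_entities
    # selected carrier rate = fold * background prevalence (capped)
    n_carrier_sel = min(int(round(fold_enrichment * prevalence * n_selected)),
                        len(carriers), n_selected)
    selected = set(rng.choice(carriers, size=n_carrier_sel, replace=False))
    selected |= set(rng.choice(others, size=n_selected - n_carrier_sel,
                               replace=False))
    truth = FixtureTruth(
        seed=seed,
        params={"n_terms": n_terms, "depth": depth,
                "n_entities": n_entities,
                "fold_enrichment": fold_enrichment,
                "n_selected": n_selected},
        enriched_term=planted_term)
    return dag, AnnotationTable(ann), selected, truth


# ---------------------------------------------------------------------------
# expression compendium fixture

def make_compendium(n_probesets: int = 200, n_arrays: int = 200,
                    modules: list[tuple[int, float]] = ((10, 0.9), (10, 0.9)),
                    seed: int = 0):
    """Expression matrix with planted co-expression modules.

    Members of a module of strength ``within_r`` share a latent factor
    with loading sqrt(within_r), so their expected pairwise Pearson r is
    within_r; non-members are independent noise.

    Returns (ExpressionCompendium, FixtureTruth).
    """
    from xhyb.coexpress import ExpressionCompendium
    rng = np.random.default_rng(seed)
    mat = rng.normal(0, 1, size=(n_probesets, n_arrays))
    planted: list[list[str]] = []
    ids = [f"PS{i + 1:05d}_at" for i in range(n_probesets)]
    start = 0
    for size, within_r in modules:
        if not 0 <= within_r < 1:
            raise ValueError("within_r must be in [0, 1)")
        factor = rng.normal(0, 1, size=n_arrays)
        idx = slice(start, start + size)
        mat[idx] = (np.sqrt(within_r) * factor
                    + np.sqrt(1 - within_r) * mat[idx])
        planted.append(ids[idx])
        start += size
    comp = ExpressionCompendium(pd.DataFrame(
        mat, index=ids, columns=[f"ARR{j + 1:04d}" for j in range(n_arrays)]))
    truth = FixtureTruth(
        seed=seed,
        params={"n_probesets": n_probesets, "n_arrays": n_arrays,
                "modules": [list(m) for m in modules]},
        modules=planted)
    return comp, truth
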