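"""Sequence-similarity baselines and leakage-controlled dataset splitting.

Consumes the standard 12-column tabular output of a local aligner
(qseqid, sseqid, pident, length, mismatch, gapopen, qstart, qend,
sstart, send, evalue, bitscore); the aligner itself is never run here.

Three roles:

* ``diamond_score`` — annotation transfer: the prediction score of class
  ``f`` for a query is the bitscore-weighted fraction of its significant
  training hits annotated with ``f``.
* ``combine_scores`` — convex combination ``α·model + (1−α)·similarity``
  of two prediction matrices, with ``α`` tunable on a validation split.
* ``similarity_split`` — proteins with pairwise identity above a
  threshold are forced into the same group (connected components of the
  identity graph) and whole groups are assigned to train/valid/test, so
  no test protein has a near-identical training relative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .metrics import fmax
from .model import PredictionMatrix
from .ontology import AnnotationSet

HIT_COLUMNS = ("qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore")

DEFAULT_EVALUE = 0.001
DEFAULT_IDENTITY_THRESHOLD = 50.0
DEFAULT_FRACTIONS = (0.81, 0.09, 0.10)


@dataclass(frozen=True)
class SimilarityHit:
    query: str
    subject: str
    bitscore: float
    evalue: float
    pident: float

    def __post_init__(self):
        if self.bitscore < 0:
            raise ValueError("bitscore must be non-negative")


@dataclass
class SplitAssignment:
    """Protein -> split label and protein -> similarity-group id."""

    split: dict[str, str]
    group: dict[str, str]

    def ids_in(self, part: str) -> list[str]:
        return [p for p, s in self.split.items() if s == part]


def read_hits(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS)
    return df


def write_split(path, assignment: "SplitAssignment",
                order: Sequence[str] | None = None):
    ids = order if order is not None else sorted(assignment.split)
    with open(path, "w") as fh:
        for pid in ids:
            fh.write(f"{pid}\t{assignment.split[pid]}\t"
                     f"{assignment.group[pid]}\n")


def read_split(path) -> "SplitAssignment":
    split, group = {}, {}
    with open(path) as fh:
        for line in fh:
            pid, part, gid = line.rstrip("\n").split("\t")
            split[pid] = part
            group[pid] = gid
    return SplitAssignment(split, group)


def write_hits(path, hits: pd.DataFrame):
    hits.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# DiamondScore
# ---------------------------------------------------------------------------

def _filter_hits(hits: pd.DataFrame, query: str, train_ids: set[str] | None,
                 evalue_max: float) -> pd.DataFrame:
    h = hits[(hits["qseqid"] == query) & (hits["sseqid"] != query)
             & (hits["evalue"] <= evalue_max)]
    if train_ids is not None:
        h = h[h["sseqid"].isin(train_ids)]
    return h


def diamond_score(query: str, hits, train_annotations: AnnotationSet,
                  class_id: str, *, train_ids: Iterable[str] | None = None,
                  evalue_max: float = DEFAULT_EVALUE) -> tuple[float, bool]:
    """Normalized-bitscore annotation transfer for one query and class.

    S(q, f) = Σ_s bitscore(q, s) · [f ∈ T_s] / Σ_s bitscore(q, s)

    over significant hits ``s`` in the training set (self-hits are
    excluded).  Returns ``(score, has_hits)``; the score is 0.0 when the
    query has no qualifying hit, which the flag distinguishes from a
    confident negative.
    """
    if isinstance(hits, (list, tuple)):
        hits = pd.DataFrame(
            [(h.query, h.subject, h.pident, 0, 0, 0, 0, 0, 0, 0,
              h.evalue, h.bitscore) for h in hits], columns=HIT_COLUMNS)
    tids = set(train_ids) if train_ids is not None else None
    h = _filter_hits(hits, query, tids, evalue_max)
    if h.empty:
        return 0.0, False
    denom = float(h["bitscore"].sum())
    if denom <= 0:
        raise ValueError(f"query {query}: all hit bitscores are zero")
    num = float(h.loc[
        h["sseqid"].map(lambda s: class_id in
                        train_annotations.annotations.get(s, ())),
        "bitscore"].sum())
    return num / denom, True


def diamond_predictions(hits: pd.DataFrame, train_annotations: AnnotationSet,
                        query_ids: Sequence[str], class_ids: Sequence[str],
                        *, train_ids: Iterable[str] | None = None,
                        evalue_max: float = DEFAULT_EVALUE) -> PredictionMatrix:
    """DiamondScore matrix over queries x classes (no-hit queries score 0)."""
    tids = set(train_ids) if train_ids is not None else None
    ci = {c: j for j, c in enumerate(class_ids)}
    scores = np.zeros((len(query_ids), len(class_ids)))
    for i, q in enumerate(query_ids):
        h = _filter_hits(hits, q, tids, evalue_max)
        if h.empty:
            continue
        denom = float(h["bitscore"].sum())
        if denom <= 0:
            raise ValueError(f"query {q}: all hit bitscores are zero")
        for _, row in h.iterrows():
            terms = train_annotations.annotations.get(row["sseqid"], ())
            w = row["bitscore"] / denom
            for t in terms:
                j = ci.get(t)
                if j is not None:
                    scores[i, j] += w
    return PredictionMatrix(list(query_ids), list(class_ids), scores)


# ---------------------------------------------------------------------------
# Score combination
# ---------------------------------------------------------------------------

def combine_scores(model: PredictionMatrix, similarity: PredictionMatrix,
                   alpha: float) -> PredictionMatrix:
    """Elementwise convex combination α·model + (1−α)·similarity.

    The similarity matrix is re-indexed onto the model matrix's rows and
    columns; missing entries contribute 0.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if not set(model.protein_ids) & set(similarity.protein_ids) and \
            similarity.protein_ids:
        raise ValueError("prediction matrices share no protein ids")
    pi = {p: i for i, p in enumerate(similarity.protein_ids)}
    ci = {c: j for j, c in enumerate(similarity.class_ids)}
    sim = np.zeros_like(model.scores)
    for i, p in enumerate(model.protein_ids):
        si = pi.get(p)
        if si is None:
            continue
        for j, c in enumerate(model.class_ids):
            sj = ci.get(c)
            if sj is not None:
                sim[i, j] = similarity.scores[si, sj]
    return PredictionMatrix(model.protein_ids, model.class_ids,
                            alpha * model.scores + (1 - alpha) * sim,
                            model.labels)


def tune_alpha(model_valid: PredictionMatrix, similarity_valid: PredictionMatrix,
               labels: np.ndarray, step: float = 0.01) -> float:
    """Pick α maximizing validation Fmax over a grid (ties -> larger α)."""
    best_a, best_f = 1.0, -1.0
    for a in np.round(np.arange(0.0, 1.0 + step / 2, step), 10):
        combined = combine_scores(model_valid, similarity_valid, float(a))
        f, _ = fmax(combined.scores, labels)
        if f >= best_f:
            best_f, best_a = f, float(a)
    return best_a


# ---------------------------------------------------------------------------
# Similarity-group splitting
# ---------------------------------------------------------------------------

def similarity_split(protein_ids: Sequence[str], hits: pd.DataFrame,
                     identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
                     fractions: Sequence[float] = DEFAULT_FRACTIONS,
                     seed: int = 0) -> SplitAssignment:
    """Group-aware train/valid/test split.

    Proteins joined by any alignment with percent identity strictly above
    ``identity_threshold`` land in the same group (connected components);
    shuffled groups are then dealt to the three splits by cumulative
    *group* fraction, so protein-level fractions may deviate slightly.
    """
    if len(protein_ids) == 0:
        raise ValueError("empty protein set")
    if not 0 < identity_threshold < 100:
        raise ValueError("identity threshold must be in (0, 100)")
    if abs(sum(fractions) - 1.0) > 1e-9 or len(fractions) != 3:
        raise ValueError("fractions must be three numbers summing to 1")
    known = set(protein_ids)
    g = nx.Graph()
    g.add_nodes_from(protein_ids)
    edges = hits[(hits["pident"] > identity_threshold)
                 & (hits["qseqid"] != hits["sseqid"])
                 & hits["qseqid"].isin(known) & hits["sseqid"].isin(known)]
    g.add_edges_from(zip(edges["qseqid"], edges["sseqid"]))
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: c[0])  # canonical order before shuffling
    rng = np.random.default_rng(seed)
    rng.shuffle(components)

    n = len(components)
    n_train = int(round(fractions[0] * n))
    n_valid = int(round((fractions[0] + fractions[1]) * n)) - n_train
    labels = ["train"] * n_train + ["valid"] * n_valid \
        + ["test"] * (n - n_train - n_valid)
    split: dict[str, str] = {}
    group: dict[str, str] = {}
    for k, (comp, lab) in enumerate(zip(components, labels)):
        gid = f"G{k:05d}"
        for p in comp:
            split[p] = lab
            group[p] = gid
    return SplitAssignment(split, group)
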