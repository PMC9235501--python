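"""Geometric ontology embedding: classes as n-balls, relations as vectors.

Every ontology class ``c`` is represented by a center vector ``fη(c)`` of
dimension ``n`` and a radius ``rη(c) ≥ 0``; every relation ``r`` by a
translation vector ``fη(r)``.  Subclass structure becomes geometry: the
four EL normal forms each induce a hinge loss that is zero exactly when
the corresponding ball configuration holds with margin ``γ``:

* NF1 ``C ⊑ D``:          ball(c) inside ball(d);
* NF2 ``C ⊓ D ⊑ E``:      the intersection region of ball(c) and ball(d)
                          close to ball(e);
* NF3 ``C ⊑ ∃R.D``:       ball(c) overlaps ball(d) translated by r;
* NF4 ``∃R.C ⊑ D``:       ball(c) translated by r inside ball(d).

A protein embedded at ``fη(p)`` is scored against class ``c`` through the
reserved ``hasFunction`` relation vector ``hF``:

    score(p, c) = σ( fη(p) · (hF + fη(c)) + rη(c) )

Radii are stored as unconstrained scalars and passed through a softplus
map, which keeps ``rη ≥ 0`` without clipping gradients.

All loss functions are written over :mod:`ontoball.autodiff` ops, so they
evaluate on plain numpy arrays and differentiate when handed Tensors —
one implementation serves both testing and training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import autodiff as ad
from .ontology import HAS_FUNCTION

__all__ = [
    "EmbeddingSpace", "LossBreakdown",
    "nf1_loss", "nf2_loss", "nf3_loss", "nf4_loss",
    "predict_score", "predict_matrix",
]


@dataclass
class LossBreakdown:
    """Per-component training loss; total is the plain sum."""

    bce: float = 0.0
    nf1: float = 0.0
    nf2: float = 0.0
    nf3: float = 0.0
    nf4: float = 0.0

    @property
    def total(self) -> float:
        return self.bce + self.nf1 + self.nf2 + self.nf3 + self.nf4

    def as_dict(self) -> dict[str, float]:
        return {"bce": self.bce, "nf1": self.nf1, "nf2": self.nf2,
                "nf3": self.nf3, "nf4": self.nf4, "total": self.total}


class EmbeddingSpace:
    """Centers, radii and relation vectors for a fixed class/relation set.

    Parameters are plain float64 arrays; the training loop temporarily
    wraps them in autodiff Tensors.  ``raw_radii`` holds the
    pre-softplus radius parameters.
    """

    def __init__(self, class_ids: Sequence[str], relation_ids: Sequence[str],
                 n: int = 1024, gamma: float = 0.1,
                 rng: np.random.Generator | None = None):
        if HAS_FUNCTION not in relation_ids:
            relation_ids = list(relation_ids) + [HAS_FUNCTION]
        self.n = int(n)
        self.gamma = float(gamma)
        self.class_ids = list(class_ids)
        self.relation_ids = list(relation_ids)
        self.class_index = {c: i for i, c in enumerate(self.class_ids)}
        self.relation_index = {r: i for i, r in enumerate(self.relation_ids)}
        if len(self.class_index) != len(self.class_ids):
            raise ValueError("duplicate class ids")
        rng = rng or np.random.default_rng(0)
        scale = 1.0 / np.sqrt(self.n)
        self.centers = rng.normal(0.0, scale, (len(self.class_ids), self.n))
        self.raw_radii = rng.normal(-1.0, 0.1, len(self.class_ids))
        self.relation_vectors = rng.normal(0.0, scale,
                                           (len(self.relation_ids), self.n))

    # -- lookups ---------------------------------------------------------
    def _cidx(self, ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self.class_index[c] for c in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"class {exc.args[0]!r} has no embedding") from None

    def _ridx(self, ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self.relation_index[r] for r in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"relation {exc.args[0]!r} has no embedding") from None

    def center(self, class_id: str) -> np.ndarray:
        return self.centers[self._cidx([class_id])[0]]

    def radius(self, class_id: str) -> float:
        return float(ad.softplus(self.raw_radii[self._cidx([class_id])[0]]))

    def relation(self, relation_id: str) -> np.ndarray:
        return self.relation_vectors[self._ridx([relation_id])[0]]

    @property
    def radii(self) -> np.ndarray:
        return ad.softplus(self.raw_radii)

    # -- persistence -----------------------------------------------------
    def save(self, path):
        """TSV export: ``id<TAB>radius<TAB>v1..vn`` (relations: empty radius)."""
        with open(path, "w") as fh:
            fh.write(f"# n={self.n}\tgamma={self.gamma}\n")
            radii = self.radii
            for cid, i in self.class_index.items():
                vec = "\t".join(f"{v:.10g}" for v in self.centers[i])
                fh.write(f"{cid}\t{radii[i]:.10g}\t{vec}\n")
            for rid, i in self.relation_index.items():
                vec = "\t".join(f"{v:.10g}" for v in self.relation_vectors[i])
                fh.write(f"{rid}\t\t{vec}\n")

    @classmethod
    def load(cls, path) -> "EmbeddingSpace":
        class_rows, rel_rows = [], []
        with open(path) as fh:
            header = fh.readline()
            meta = dict(kv.split("=") for kv in header.lstrip("# ").split("\t"))
            n, gamma = int(meta["n"]), float(meta["gamma"])
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ident, radius, vec = parts[0], parts[1], np.array(parts[2:], dtype=float)
                if radius == "":
                    rel_rows.append((ident, vec))
                else:
                    class_rows.append((ident, float(radius), vec))
        space = cls([c for c, _, _ in class_rows], [r for r, _ in rel_rows],
                    n=n, gamma=gamma)
        space.centers = np.array([v for _, _, v in class_rows])
        # invert the softplus map: raw = log(exp(r) - 1)
        r = np.clip(np.array([rr for _, rr, _ in class_rows]), 1e-10, None)
        space.raw_radii = r + np.log1p(-np.exp(-r))
        space.relation_vectors = np.array([v for _, v in rel_rows])
        return space


# ---------------------------------------------------------------------------
# Normal-form losses
# ---------------------------------------------------------------------------
# Each takes optional ``centers``/``raw_radii``/``relations`` overrides so
# the training loop can substitute autodiff Tensors (possibly after batch
# normalization) for the stored arrays.

def _params(space, centers, raw_radii, relations):
    c = space.centers if centers is None else centers
    r = space.raw_radii if raw_radii is None else raw_radii
    v = space.relation_vectors if relations is None else relations
    return c, ad.softplus(r), v


def nf1_loss(space: EmbeddingSpace, pairs: Sequence[tuple],
             centers=None, raw_radii=None, relations=None):
    """Mean hinge on ball containment for C ⊑ D axioms.

    max(0, ‖fη(c) − fη(d)‖ + rη(c) − rη(d) − γ): zero when ball(c) lies
    inside ball(d) with slack γ.
    """
    if len(pairs) == 0:
        return 0.0
    C, R, _ = _params(space, centers, raw_radii, relations)
    ic = space._cidx([c for c, _ in pairs])
    id_ = space._cidx([d for _, d in pairs])
    dist = ad.l2norm(ad.sub(ad.take_rows(C, ic), ad.take_rows(C, id_)))
    slack = ad.sub(ad.add(dist, ad.take_rows(R, ic)),
                   ad.add(ad.take_rows(R, id_), space.gamma))
    return ad.tmean(ad.maximum(slack, 0.0))


def nf2_loss(space: EmbeddingSpace, triples: Sequence[tuple],
             centers=None, raw_radii=None, relations=None):
    """Mean four-term hinge for conjunction axioms C ⊓ D ⊑ E.

    Pulls ball(e) toward the intersection region of ball(c) and ball(d):
    the balls for c and d must overlap, e must be near both, and the
    radius of e must cover the smaller of the two.
    """
    if len(triples) == 0:
        return 0.0
    C, R, _ = _params(space, centers, raw_radii, relations)
    ic = space._cidx([c for c, _, _ in triples])
    id_ = space._cidx([d for _, d, _ in triples])
    ie = space._cidx([e for _, _, e in triples])
    fc, fd, fe = (ad.take_rows(C, i) for i in (ic, id_, ie))
    rc, rd, re = (ad.take_rows(R, i) for i in (ic, id_, ie))
    g = space.gamma
    t1 = ad.maximum(ad.sub(ad.l2norm(ad.sub(fc, fd)),
                           ad.add(ad.add(rc, rd), g)), 0.0)
    t2 = ad.maximum(ad.sub(ad.l2norm(ad.sub(fc, fe)), ad.add(rc, g)), 0.0)
    t3 = ad.maximum(ad.sub(ad.l2norm(ad.sub(fd, fe)), ad.add(rc, g)), 0.0)
    t4 = ad.maximum(ad.sub(ad.minimum(rc, rd), ad.add(re, g)), 0.0)
    return ad.tmean(ad.add(ad.add(t1, t2), ad.add(t3, t4)))


def nf3_loss(space: EmbeddingSpace, triples: Sequence[tuple],
             centers=None, raw_radii=None, relations=None):
    """Mean hinge for existential axioms C ⊑ ∃R.D (entries ``(c, r, d)``).

    Ball(d) is translated by the relation vector; the loss vanishes when
    the translated ball overlaps ball(c) within margin γ.
    """
    if len(triples) == 0:
        return 0.0
    C, R, V = _params(space, centers, raw_radii, relations)
    ic = space._cidx([c for c, _, _ in triples])
    ir = space._ridx([r for _, r, _ in triples])
    id_ = space._cidx([d for _, _, d in triples])
    diff = ad.sub(ad.sub(ad.take_rows(C, ic), ad.take_rows(V, ir)),
                  ad.take_rows(C, id_))
    slack = ad.sub(ad.l2norm(diff),
                   ad.add(ad.add(ad.take_rows(R, ic), ad.take_rows(R, id_)),
                          space.gamma))
    return ad.tmean(ad.maximum(slack, 0.0))


def nf4_loss(space: EmbeddingSpace, triples: Sequence[tuple],
             centers=None, raw_radii=None, relations=None):
    """Mean hinge for axioms ∃R.C ⊑ D (entries ``(r, c, d)``).

    Ball(c) translated by the relation vector must lie inside ball(d).
    """
    if len(triples) == 0:
        return 0.0
    C, R, V = _params(space, centers, raw_radii, relations)
    ir = space._ridx([r for r, _, _ in triples])
    ic = space._cidx([c for _, c, _ in triples])
    id_ = space._cidx([d for _, _, d in triples])
    diff = ad.sub(ad.add(ad.take_rows(C, ic), ad.take_rows(V, ir)),
                  ad.take_rows(C, id_))
    slack = ad.sub(ad.add(ad.l2norm(diff), ad.take_rows(R, ic)),
                   ad.add(ad.take_rows(R, id_), space.gamma))
    return ad.tmean(ad.maximum(slack, 0.0))


# ---------------------------------------------------------------------------
# Prediction score
# ---------------------------------------------------------------------------

def prediction_logits(space: EmbeddingSpace, protein_embeddings,
                      class_ids: Sequence[str],
                      centers=None, raw_radii=None, relations=None):
    """Pre-sigmoid scores, shape (proteins, classes).

    logit(p, c) = fη(p) · (hF + fη(c)) + rη(c)
    """
    C, R, V = _params(space, centers, raw_radii, relations)
    ic = space._cidx(class_ids)
    hf = ad.take_rows(V, space._ridx([HAS_FUNCTION]))  # (1, n)
    targets = ad.add(ad.take_rows(C, ic), hf)          # (k, n)
    dots = ad.matmul(protein_embeddings, _transpose(targets))
    return ad.add(dots, ad.take_rows(R, ic))


def _transpose(x):
    if isinstance(x, ad.Tensor):
        out = x.value.T

        def backward(g):
            ad._accum(x, g.T)

        return ad.Tensor(out, (x,), backward)
    return np.asarray(x).T


def predict_matrix(space: EmbeddingSpace, protein_embeddings,
                   class_ids: Sequence[str],
                   centers=None, raw_radii=None, relations=None):
    """Sigmoid scores in (0,1), shape (proteins, classes)."""
    emb = np.atleast_2d(protein_embeddings) \
        if not isinstance(protein_embeddings, ad.Tensor) else protein_embeddings
    if not isinstance(emb, ad.Tensor) and emb.shape[1] != space.n:
        raise ValueError(
            f"protein embedding dimension {emb.shape[1]} != space n={space.n}")
    return ad.sigmoid(prediction_logits(space, emb, class_ids,
                                        centers, raw_radii, relations))


def predict_score(space: EmbeddingSpace, protein_embedding: np.ndarray,
                  class_id: str) -> float:
    """Score a single protein embedding against a single class."""
    emb = np.asarray(protein_embedding, dtype=float)
    if emb.ndim != 1 or emb.shape[0] != space.n:
        raise ValueError(
            f"protein embedding must have length n={space.n}, got {emb.shape}")
    return float(predict_matrix(space, emb[None, :], [class_id])[0, 0])
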