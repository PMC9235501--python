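"""Protein function prediction by joint protein/ontology embedding.

A protein is represented as a binary vector over a domain-signature
vocabulary (e.g. InterPro hits).  A residual two-block MLP

    h   = MLPBlock1(x)          MLPBlock(x) = DropOut(BatchNorm(ReLU(Wx+b)))
    emb = h + MLPBlock2(h)

projects it into the same n-dimensional space in which the ontology
classes live as n-balls (:mod:`ontoball.geometry`).  Training jointly
minimizes the binary cross-entropy of the geometric prediction score
against the propagated labels and the four normal-form losses that keep
the class balls consistent with the ontology axioms:

    L = BCE + L_NF1 + L_NF2 + L_NF3 + L_NF4

Because the class embeddings are constrained by axioms shared with
trained classes, a class that never had an annotated training protein
still receives a meaningful ball — scoring proteins against it yields
*zero-shot* predictions.

The module is organized around two objects in the statsmodels style:
:class:`FunctionPredictionModel` holds the data and architecture choice
("elembed" for the geometric model, "mlp" for the plain sigmoid-head
baseline); :meth:`FunctionPredictionModel.fit` runs Adam and returns a
:class:`FunctionPredictionResults` carrying the trained parameters,
per-epoch loss history, prediction and evaluation methods, and a
``summary()`` table.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import autodiff as ad
from . import geometry, metrics
from .geometry import EmbeddingSpace, LossBreakdown
from .ontology import AnnotationSet, NormalizedAxiomSet, propagate

__all__ = [
    "ProteinRecord", "PredictionMatrix", "TrainConfig", "Dataset",
    "MLPBlock", "ProteinEncoder", "encode_protein",
    "FunctionPredictionModel", "FunctionPredictionResults",
    "joint_loss", "propagate_scores", "zero_shot_protocol",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ProteinRecord:
    """One protein: id, binary feature vector, propagated annotations."""

    id: str
    features: np.ndarray
    annotations: set[str] = field(default_factory=set)
    group_id: str | None = None


@dataclass
class PredictionMatrix:
    """Proteins x classes score matrix with an optional aligned label matrix."""

    protein_ids: list[str]
    class_ids: list[str]
    scores: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.protein_ids), len(self.class_ids)):
            raise ValueError("score matrix shape does not match id lists")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=bool)
            if self.labels.shape != self.scores.shape:
                raise ValueError("label matrix shape does not match scores")
        if not np.isfinite(self.scores).all():
            raise ValueError("non-finite prediction scores")

    def to_tsv(self, path, min_score: float = 0.0):
        with open(path, "w") as fh:
            for i, pid in enumerate(self.protein_ids):
                for j, cid in enumerate(self.class_ids):
                    s = self.scores[i, j]
                    if s >= min_score:
                        fh.write(f"{pid}\t{cid}\t{s:.6f}\n")

    @classmethod
    def from_tsv(cls, path, protein_ids=None, class_ids=None,
                 labels=None) -> "PredictionMatrix":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["protein_id", "go_id", "score"])
        pids = protein_ids or sorted(df["protein_id"].unique())
        cids = class_ids or sorted(df["go_id"].unique())
        pi = {p: i for i, p in enumerate(pids)}
        ci = {c: j for j, c in enumerate(cids)}
        scores = np.zeros((len(pids), len(cids)))
        for p, c, s in df.itertuples(index=False):
            if p in pi and c in ci:
                scores[pi[p], ci[c]] = s
        return cls(list(pids), list(cids), scores, labels)


@dataclass
class Dataset:
    """Everything a training run needs, in memory.

    ``raw_annotations`` are *pre-propagation* experimental annotations;
    ``split`` maps protein id to one of train/valid/test.
    """

    protein_ids: list[str]
    features: np.ndarray                 # (N, V) binary
    raw_annotations: AnnotationSet
    nf: NormalizedAxiomSet
    closure: Mapping[str, set[str]]
    split: Mapping[str, str]
    namespace_classes: Sequence[str] | None = None  # restrict targets

    def ids_in(self, part: str) -> list[str]:
        return [p for p in self.protein_ids if self.split.get(p) == part]

    def feature_rows(self, ids: Sequence[str]) -> np.ndarray:
        index = {p: i for i, p in enumerate(self.protein_ids)}
        return self.features[[index[p] for p in ids]]

    def propagated(self) -> AnnotationSet:
        return propagate(self.raw_annotations, self.closure)


@dataclass
class TrainConfig:
    """Optimization settings; the loss, not the schedule, is the contract."""

    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 100
    patience: int = 10
    dropout: float = 0.5
    seed: int = 0
    gamma: float = 0.1              # margin of the normal-form losses
    n: int = 1024                   # embedding dimension
    nf_batch_size: int = 256        # per-step sample from each NF list
    checkpoint_metric: str = "fmax"  # or "loss"
    min_annotations: int = 1        # target-class annotation threshold
    class_batchnorm: bool = True    # batch-normalize class centers
    device: str = "cpu"

    def __post_init__(self):
        for name in ("lr", "batch_size", "epochs", "dropout", "n"):
            if getattr(self, name) < 0:
                raise ValueError(f"TrainConfig.{name} must be non-negative")
        if self.checkpoint_metric not in ("fmax", "loss"):
            raise ValueError("checkpoint_metric must be 'fmax' or 'loss'")

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def fixture(cls, seed: int = 0, **overrides) -> "TrainConfig":
        """Settings sized for the synthetic desk-scale fixture.

        A 64-dimensional space is ample for ~60 classes, and with only a
        few optimizer steps per epoch the schedule runs long (300 epochs,
        patience 40) to reach convergence; one fit takes a few seconds on
        a single CPU.
        """
        defaults = dict(n=64, epochs=300, patience=40, seed=seed)
        defaults.update(overrides)
        return cls(**defaults)


# ---------------------------------------------------------------------------
# Network building blocks (autodiff-backed)
# ---------------------------------------------------------------------------

class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.W = ad.Parameter(rng.normal(0.0, scale, (d_in, d_out)), name="W")
        self.b = ad.Parameter(np.zeros(d_out), name="b")

    def __call__(self, x):
        return ad.add(ad.matmul(x, self.W), self.b)

    def parameters(self):
        return [self.W, self.b]


class BatchNorm:
    """Feature-wise batch normalization with running statistics."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = ad.Parameter(np.ones(dim), name="bn_gamma")
        self.beta = ad.Parameter(np.zeros(dim), name="bn_beta")
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x, training: bool):
        if training:
            mean = ad.tmean(x, axis=0)
            centered = ad.sub(x, mean)
            var = ad.tmean(ad.square(centered), axis=0)
            mv, vv = ad._val(mean), ad._val(var)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mv
            self.running_var = (1 - m) * self.running_var + m * vv
        else:
            mean, var = self.running_mean, self.running_var
            centered = ad.sub(x, mean)
        inv = ad.div(1.0, ad.sqrt(ad.add(var, self.eps)))
        return ad.add(ad.mul(ad.mul(centered, inv), self.gamma), self.beta)

    def parameters(self):
        return [self.gamma, self.beta]

    def state(self):
        return (self.running_mean.copy(), self.running_var.copy())

    def set_state(self, state):
        self.running_mean, self.running_var = (s.copy() for s in state)


class MLPBlock:
    """DropOut(BatchNorm(ReLU(Wx + b))), in exactly that order.

    In evaluation mode dropout is the identity and normalization uses the
    running statistics.
    """

    def __init__(self, d_in: int, d_out: int, dropout: float,
                 rng: np.random.Generator):
        self.linear = Linear(d_in, d_out, rng)
        self.bn = BatchNorm(d_out)
        self.dropout = dropout

    def __call__(self, x, training: bool = False,
                 rng: np.random.Generator | None = None):
        h = self.bn(ad.relu(self.linear(x)), training)
        if training and self.dropout > 0:
            if rng is None:
                raise ValueError("training-mode dropout needs an rng")
            keep = 1.0 - self.dropout
            mask = (rng.random(ad._val(h).shape) < keep) / keep
            h = ad.mul(h, mask)
        return h

    def parameters(self):
        return self.linear.parameters() + self.bn.parameters()


class ProteinEncoder:
    """Residual two-block MLP: emb = h + MLPBlock2(h), h = MLPBlock1(x)."""

    def __init__(self, vocab_size: int, n: int, dropout: float,
                 rng: np.random.Generator):
        self.vocab_size = vocab_size
        self.n = n
        self.block1 = MLPBlock(vocab_size, n, dropout, rng)
        self.block2 = MLPBlock(n, n, dropout, rng)

    def __call__(self, x, training: bool = False,
                 rng: np.random.Generator | None = None):
        xv = x if isinstance(x, ad.Tensor) else np.atleast_2d(np.asarray(x, float))
        if ad._val(xv).shape[1] != self.vocab_size:
            raise ValueError(
                f"feature length {ad._val(xv).shape[1]} != vocabulary "
                f"size {self.vocab_size}")
        h = self.block1(xv, training, rng)
        return ad.add(h, self.block2(h, training, rng))

    def parameters(self):
        return self.block1.parameters() + self.block2.parameters()


def encode_protein(encoder: ProteinEncoder, x) -> np.ndarray:
    """Evaluation-mode protein embedding(s) for binary feature vector(s)."""
    return np.atleast_2d(ad._val(encoder(x, training=False)))


def _bce_from_logits(logits, y):
    """Mean binary cross-entropy, computed stably from logits."""
    per = ad.sub(ad.softplus(logits), ad.mul(y, logits))
    return ad.tmean(per)


# ---------------------------------------------------------------------------
# Loss evaluation (public, evaluation-mode)
# ---------------------------------------------------------------------------

def joint_loss(space: EmbeddingSpace, encoder: ProteinEncoder,
               features: np.ndarray, labels: np.ndarray,
               target_classes: Sequence[str], nf: NormalizedAxiomSet,
               center_bn: "BatchNorm | None" = None) -> LossBreakdown:
    """Evaluation-mode loss breakdown over a batch and the full NF lists."""
    emb = encode_protein(encoder, features)
    centers = space.centers if center_bn is None else \
        ad._val(center_bn(space.centers, training=False))
    logits = geometry.prediction_logits(space, emb, target_classes,
                                        centers=centers)
    y = np.asarray(labels, dtype=float)
    bd = LossBreakdown(
        bce=float(_bce_from_logits(logits, y)),
        nf1=float(geometry.nf1_loss(space, nf.nf1, centers=centers)),
        nf2=float(geometry.nf2_loss(space, nf.nf2, centers=centers)),
        nf3=float(geometry.nf3_loss(space, nf.nf3, centers=centers)),
        nf4=float(geometry.nf4_loss(space, nf.nf4, centers=centers)),
    )
    if not np.isfinite(bd.total):
        raise FloatingPointError("non-finite loss component (divergence)")
    return bd


def propagate_scores(matrix: PredictionMatrix,
                     closure: Mapping[str, set[str]]) -> PredictionMatrix:
    """Hierarchical max-propagation: ancestor score >= descendant score."""
    idx = {c: j for j, c in enumerate(matrix.class_ids)}
    scores = matrix.scores.copy()
    # ascending ancestor-set size puts children before their parents
    order = sorted(matrix.class_ids, key=lambda c: len(closure.get(c, ())))
    for cid in order:
        j = idx[cid]
        for anc in closure.get(cid, ()):  # closure includes cid itself
            k = idx.get(anc)
            if k is not None and k != j:
                np.maximum(scores[:, k], scores[:, j], out=scores[:, k])
    return PredictionMatrix(matrix.protein_ids, matrix.class_ids, scores,
                            matrix.labels)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class FunctionPredictionModel:
    """Joint protein/ontology embedding model over a fixed dataset.

    Parameters
    ----------
    train, valid : list of ProteinRecord
        Disjoint protein sets; ``annotations`` must be propagated.
    nf : NormalizedAxiomSet
        Normalized ontology axioms; every class mentioned gets a ball.
    model_type : "elembed" or "mlp"
        Geometric scoring with normal-form losses, or the plain MLP
        baseline with a sigmoid classification head and no axiom losses.
    exclude_targets : class ids never used in the BCE term (they still
        participate in the axiom losses — the zero-shot mechanism).
    """

    def __init__(self, train: Sequence[ProteinRecord],
                 valid: Sequence[ProteinRecord],
                 nf: NormalizedAxiomSet,
                 model_type: str = "elembed",
                 exclude_targets: Iterable[str] = (),
                 class_universe: Iterable[str] | None = None):
        if model_type not in ("elembed", "mlp"):
            raise ValueError(f"unknown model_type {model_type!r}")
        train_ids = {p.id for p in train}
        if train_ids & {p.id for p in valid}:
            raise ValueError("train and valid protein sets overlap")
        self.train = list(train)
        self.valid = list(valid)
        self.nf = nf
        self.model_type = model_type
        self.exclude_targets = set(exclude_targets)
        universe = set(class_universe or ())
        universe |= nf.all_class_ids()
        for p in self.train:
            universe |= p.annotations
        self.class_ids = sorted(universe)
        self.relation_ids = sorted(nf.all_relation_ids())
        self.vocab_size = int(self.train[0].features.shape[0])

    @classmethod
    def from_dataset(cls, dataset: Dataset, model_type: str = "elembed",
                     exclude_targets: Iterable[str] = (),
                     annotations: AnnotationSet | None = None
                     ) -> "FunctionPredictionModel":
        """Build train/valid records from a :class:`Dataset`.

        ``annotations`` overrides the dataset's propagated annotations
        (used by the zero-shot protocol to train on censored labels).
        """
        ann = annotations if annotations is not None else dataset.propagated()
        index = {p: i for i, p in enumerate(dataset.protein_ids)}

        def records(part):
            return [ProteinRecord(p, dataset.features[index[p]],
                                  set(ann.annotations.get(p, ())))
                    for p in dataset.ids_in(part)]

        exclude = set(exclude_targets)
        if dataset.namespace_classes is not None:
            allowed = set(dataset.namespace_classes)
            annotated = set().union(*ann.annotations.values()) \
                if ann.annotations else set()
            exclude |= annotated - allowed
        return cls(records("train"), records("valid"), dataset.nf,
                   model_type=model_type, exclude_targets=exclude)

    # -- fitting ---------------------------------------------------------
    def target_classes(self, min_annotations: int = 1) -> list[str]:
        counts: dict[str, int] = {}
        for p in self.train:
            for c in p.annotations:
                counts[c] = counts.get(c, 0) + 1
        fresh = set(self.nf.fresh_classes)
        targets = sorted(
            c for c, k in counts.items()
            if k >= min_annotations and c not in fresh
            and c not in self.exclude_targets)
        return targets

    def fit(self, config: TrainConfig | None = None, verbose: bool = False
            ) -> "FunctionPredictionResults":
        config = config or TrainConfig()
        rng = np.random.default_rng(config.seed)
        targets = self.target_classes(config.min_annotations)
        if not targets:
            raise ValueError("no target class has enough training annotations")

        space = EmbeddingSpace(self.class_ids, self.relation_ids,
                               n=config.n, gamma=config.gamma, rng=rng)
        encoder = ProteinEncoder(self.vocab_size, config.n, config.dropout, rng)

        Xtr = np.stack([p.features for p in self.train]).astype(float)
        Ytr = self._labels(self.train, targets)
        Xva = np.stack([p.features for p in self.valid]).astype(float) \
            if self.valid else None
        Yva = self._labels(self.valid, targets) if self.valid else None

        params = list(encoder.parameters())
        center_bn = None
        head = None
        if self.model_type == "elembed":
            centers_p = ad.Parameter(space.centers, name="centers")
            radii_p = ad.Parameter(space.raw_radii, name="raw_radii")
            rel_p = ad.Parameter(space.relation_vectors, name="relations")
            params += [centers_p, radii_p, rel_p]
            if config.class_batchnorm:
                center_bn = BatchNorm(config.n)
                params += center_bn.parameters()
        else:
            head = Linear(config.n, len(targets), rng)
            params += head.parameters()
        opt = ad.Adam(params, lr=config.lr)

        nf_lists = [self.nf.nf1, self.nf.nf2, self.nf.nf3, self.nf.nf4]
        nf_fns = [geometry.nf1_loss, geometry.nf2_loss,
                  geometry.nf3_loss, geometry.nf4_loss]

        def forward(xb, yb, training, nf_sample):
            emb = encoder(xb, training=training, rng=rng)
            parts = {}
            if self.model_type == "elembed":
                centers = centers_p
                if center_bn is not None:
                    centers = center_bn(centers_p, training)
                logits = geometry.prediction_logits(
                    space, emb, targets, centers=centers,
                    raw_radii=radii_p, relations=rel_p)
                total = _bce_from_logits(logits, yb)
                parts["bce"] = float(ad._val(total))
                for name, fn, lst in zip(("nf1", "nf2", "nf3", "nf4"),
                                         nf_fns, nf_lists):
                    sub = lst
                    if nf_sample and len(lst) > config.nf_batch_size:
                        pick = rng.choice(len(lst), config.nf_batch_size,
                                          replace=False)
                        sub = [lst[i] for i in pick]
                    term = fn(space, sub, centers=centers,
                              raw_radii=radii_p, relations=rel_p)
                    parts[name] = float(ad._val(term))
                    total = ad.add(total, term)
            else:
                logits = head(emb)
                total = _bce_from_logits(logits, yb)
                parts["bce"] = float(ad._val(total))
            return total, parts

        history: list[dict] = []
        best_metric, best_epoch, best_state = -np.inf, -1, None
        bad_epochs = 0
        n_train = len(self.train)

        def snapshot():
            state = {"params": [p.value.copy() for p in params],
                     "bns": [bn.state() for bn in self._bns(encoder, center_bn)]}
            return state

        def restore(state):
            for p, v in zip(params, state["params"]):
                p.value = v.copy()
            for bn, s in zip(self._bns(encoder, center_bn), state["bns"]):
                bn.set_state(s)

        for epoch in range(config.epochs):
            perm = rng.permutation(n_train)
            epoch_parts: dict[str, float] = {}
            n_batches = 0
            for start in range(0, n_train, config.batch_size):
                idx = perm[start:start + config.batch_size]
                opt.zero_grad()
                total, parts = forward(Xtr[idx], Ytr[idx].astype(float),
                                       training=True, nf_sample=True)
                if not np.isfinite(ad._val(total)):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch}")
                total.backward(seed=np.ones(()))
                opt.step()
                for k, v in parts.items():
                    epoch_parts[k] = epoch_parts.get(k, 0.0) + v
                n_batches += 1
            # write learned values back so evaluation-mode helpers see them
            if self.model_type == "elembed":
                space.centers = centers_p.value
                space.raw_radii = radii_p.value
                space.relation_vectors = rel_p.value

            record = {k: v / n_batches for k, v in epoch_parts.items()}
            record["epoch"] = epoch
            record["total"] = sum(v for k, v in record.items() if k != "epoch")

            if Xva is not None and len(Xva):
                val_scores = self._scores_eval(space, encoder, center_bn,
                                               head, Xva, targets)
                vf, _ = metrics.fmax(val_scores, Yva)
                record["valid_fmax"] = vf
                val_bce = float(_bce_from_logits(
                    _logit(val_scores), Yva.astype(float)))
                record["valid_loss"] = val_bce
                metric = vf if config.checkpoint_metric == "fmax" else -val_bce
            else:
                metric = -record["total"]
            history.append(record)
            if verbose:
                print(f"epoch {epoch:3d}  total {record['total']:.4f}  "
                      f"valid_fmax {record.get('valid_fmax', float('nan')):.3f}")

            if metric > best_metric + 1e-9:
                best_metric, best_epoch = metric, epoch
                best_state = snapshot()
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > config.patience:
                    break

        if best_state is not None:
            restore(best_state)
            if self.model_type == "elembed":
                space.centers = centers_p.value
                space.raw_radii = radii_p.value
                space.relation_vectors = rel_p.value

        return FunctionPredictionResults(
            model=self, config=config, space=space, encoder=encoder,
            center_bn=center_bn, head=head, targets=targets,
            history=history, best_epoch=best_epoch)

    # -- helpers ---------------------------------------------------------
    @staticmethod
    def _bns(encoder, center_bn):
        bns = [encoder.block1.bn, encoder.block2.bn]
        if center_bn is not None:
            bns.append(center_bn)
        return bns

    def _labels(self, records: Sequence[ProteinRecord],
                targets: Sequence[str]) -> np.ndarray:
        return label_matrix(records, targets)

    def _scores_eval(self, space, encoder, center_bn, head, X, class_ids):
        return _eval_scores(self.model_type, space, encoder, center_bn,
                            head, X, class_ids)


def label_matrix(records: Sequence[ProteinRecord],
                 targets: Sequence[str]) -> np.ndarray:
    ci = {c: j for j, c in enumerate(targets)}
    y = np.zeros((len(records), len(targets)), dtype=bool)
    for i, rec in enumerate(records):
        for c in rec.annotations:
            j = ci.get(c)
            if j is not None:
                y[i, j] = True
    return y


def _eval_scores(model_type, space, encoder, center_bn, head, X, class_ids):
    emb = encode_protein(encoder, X)
    if model_type == "elembed":
        centers = space.centers if center_bn is None else \
            ad._val(center_bn(space.centers, training=False))
        return ad._val(geometry.predict_matrix(space, emb, class_ids,
                                               centers=centers))
    return ad._val(ad.sigmoid(head(emb)))


def _logit(p, eps=1e-12):
    p = np.clip(p, eps, 1 - eps)
    return np.log(p / (1 - p))


class FunctionPredictionResults:
    """Trained parameters plus prediction, evaluation and reporting.

    ``model`` is the fitting :class:`FunctionPredictionModel`; results
    reloaded from a checkpoint carry ``model=None`` and support
    prediction but not data-dependent reporting.
    """

    def __init__(self, model, config, space, encoder, center_bn, head,
                 targets, history, best_epoch):
        self.model = model
        self.config = config
        self.space = space
        self.encoder = encoder
        self.center_bn = center_bn
        self.head = head
        self.targets = targets
        self.history = history
        self.best_epoch = best_epoch
        self._model_type = model.model_type if model is not None else \
            ("elembed" if head is None else "mlp")

    # -- core inference --------------------------------------------------
    def encode(self, features) -> np.ndarray:
        return encode_protein(self.encoder, features)

    def embedding_space(self) -> EmbeddingSpace:
        """The trained space with frozen center normalization applied."""
        out = copy.deepcopy(self.space)
        if self.center_bn is not None:
            out.centers = ad._val(self.center_bn(out.centers, training=False))
        return out

    def predict(self, proteins, class_ids: Sequence[str] | None = None,
                propagate: bool = False,
                closure: Mapping[str, set[str]] | None = None
                ) -> PredictionMatrix:
        """Score proteins against classes.

        ``proteins`` is a list of :class:`ProteinRecord` or a feature
        matrix.  For the geometric model any embedded class may be
        requested — including classes absent from the training labels
        (zero-shot); the MLP baseline can only score its trained targets.
        With ``propagate=True`` scores are max-propagated so that every
        ancestor scores at least as high as its descendants.
        """
        if isinstance(proteins, (list, tuple)) and proteins and \
                isinstance(proteins[0], ProteinRecord):
            ids = [p.id for p in proteins]
            X = np.stack([p.features for p in proteins]).astype(float)
            labels_src = proteins
        else:
            X = np.atleast_2d(np.asarray(proteins, dtype=float))
            ids = [f"protein_{i}" for i in range(X.shape[0])]
            labels_src = None
        class_ids = list(class_ids) if class_ids is not None else list(self.targets)
        if self.model_type == "mlp":
            missing = [c for c in class_ids if c not in set(self.targets)]
            if missing:
                raise KeyError(
                    f"MLP baseline cannot score untrained classes: {missing[:5]}")
            cols = [self.targets.index(c) for c in class_ids]
            scores = _eval_scores(self.model_type, self.space, self.encoder,
                                  self.center_bn, self.head, X,
                                  self.targets)[:, cols]
        else:
            scores = _eval_scores(self.model_type, self.space, self.encoder,
                                  self.center_bn, self.head, X, class_ids)
        labels = None
        if labels_src is not None:
            labels = label_matrix(labels_src, class_ids)
        out = PredictionMatrix(ids, class_ids, scores, labels)
        if propagate:
            if closure is None:
                raise ValueError("score propagation needs the ancestor closure")
            out = propagate_scores(out, closure)
        return out

    @property
    def model_type(self) -> str:
        return self._model_type

    # -- reporting -------------------------------------------------------
    def loss_breakdown(self, records: Sequence[ProteinRecord] | None = None
                       ) -> LossBreakdown:
        if records is None:
            if self.model is None:
                raise ValueError("a reloaded checkpoint needs explicit records")
            records = self.model.train
        records = list(records)
        X = np.stack([p.features for p in records]).astype(float)
        Y = label_matrix(records, self.targets)
        if self.model_type == "elembed":
            if self.model is None:
                raise ValueError("loss breakdown needs the fitting model")
            return joint_loss(self.space, self.encoder, X, Y, self.targets,
                              self.model.nf, center_bn=self.center_bn)
        emb = self.encode(X)
        return LossBreakdown(bce=float(_bce_from_logits(
            ad._val(self.head(emb)), Y.astype(float))))

    def evaluate(self, records: Sequence[ProteinRecord],
                 class_ids: Sequence[str] | None = None,
                 ic: Mapping[str, float] | None = None,
                 exclude_classes: Sequence[str] = ()) -> metrics.EvaluationResult:
        class_ids = list(class_ids) if class_ids is not None else list(self.targets)
        pred = self.predict(records, class_ids)
        return metrics.evaluate_all(pred, class_ids=class_ids, ic=ic,
                                    exclude_classes=exclude_classes)

    def summary(self) -> str:
        bd = self.loss_breakdown()
        last = self.history[-1] if self.history else {}
        rows = [
            ("model", self.model_type),
            ("embedding dim n", str(self.config.n)),
            ("margin gamma", f"{self.config.gamma}"),
            ("target classes", str(len(self.targets))),
            ("embedded classes", str(len(self.space.class_ids))),
            ("train proteins",
             str(len(self.model.train)) if self.model else "n/a"),
            ("epochs run", str(len(self.history))),
            ("best epoch", str(self.best_epoch)),
            ("valid Fmax", f"{last.get('valid_fmax', float('nan')):.3f}"),
            ("loss (bce)", f"{bd.bce:.4f}"),
            ("loss (nf1..4)", f"{bd.nf1:.4f} {bd.nf2:.4f} "
                              f"{bd.nf3:.4f} {bd.nf4:.4f}"),
            ("loss (total)", f"{bd.total:.4f}"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Function prediction results", "=" * 28]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)

    def save(self, outdir):
        """Checkpoint directory: embedding TSV, config YAML, weight arrays."""
        import pathlib
        import yaml
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.embedding_space().save(out / "embeddings.tsv")
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump({"model_type": self.model_type,
                            "targets": list(self.targets),
                            "class_ids": list(self.space.class_ids),
                            "relation_ids": list(self.space.relation_ids),
                            "best_epoch": self.best_epoch,
                            "vocab_size": self.encoder.vocab_size,
                            "config": self.config.as_dict()}, fh)
        arrays = {
            "space_centers": self.space.centers,
            "space_raw_radii": self.space.raw_radii,
            "space_relations": self.space.relation_vectors,
        }
        for prefix, block in (("b1", self.encoder.block1),
                              ("b2", self.encoder.block2)):
            arrays[f"{prefix}_W"] = block.linear.W.value
            arrays[f"{prefix}_b"] = block.linear.b.value
            arrays[f"{prefix}_bn_gamma"] = block.bn.gamma.value
            arrays[f"{prefix}_bn_beta"] = block.bn.beta.value
            arrays[f"{prefix}_bn_mean"] = block.bn.running_mean
            arrays[f"{prefix}_bn_var"] = block.bn.running_var
        if self.center_bn is not None:
            arrays["cbn_gamma"] = self.center_bn.gamma.value
            arrays["cbn_beta"] = self.center_bn.beta.value
            arrays["cbn_mean"] = self.center_bn.running_mean
            arrays["cbn_var"] = self.center_bn.running_var
        if self.head is not None:
            arrays["head_W"] = self.head.W.value
            arrays["head_b"] = self.head.b.value
        np.savez(out / "weights.npz", **arrays)

    @classmethod
    def load(cls, outdir) -> "FunctionPredictionResults":
        """Rebuild a prediction-capable results object from a checkpoint."""
        import pathlib
        import yaml
        out = pathlib.Path(outdir)
        with open(out / "config.yaml") as fh:
            meta = yaml.safe_load(fh)
        config = TrainConfig(**meta["config"])
        z = np.load(out / "weights.npz")
        rng = np.random.default_rng(0)
        space = EmbeddingSpace(meta["class_ids"], meta["relation_ids"],
                               n=config.n, gamma=config.gamma, rng=rng)
        space.centers = z["space_centers"]
        space.raw_radii = z["space_raw_radii"]
        space.relation_vectors = z["space_relations"]
        encoder = ProteinEncoder(meta["vocab_size"], config.n,
                                 config.dropout, rng)
        for prefix, block in (("b1", encoder.block1), ("b2", encoder.block2)):
            block.linear.W.value = z[f"{prefix}_W"]
            block.linear.b.value = z[f"{prefix}_b"]
            block.bn.gamma.value = z[f"{prefix}_bn_gamma"]
            block.bn.beta.value = z[f"{prefix}_bn_beta"]
            block.bn.running_mean = z[f"{prefix}_bn_mean"]
            block.bn.running_var = z[f"{prefix}_bn_var"]
        center_bn = None
        if "cbn_gamma" in z:
            center_bn = BatchNorm(config.n)
            center_bn.gamma.value = z["cbn_gamma"]
            center_bn.beta.value = z["cbn_beta"]
            center_bn.running_mean = z["cbn_mean"]
            center_bn.running_var = z["cbn_var"]
        head = None
        if "head_W" in z:
            head = Linear(config.n, len(meta["targets"]),
                          np.random.default_rng(0))
            head.W.value = z["head_W"]
            head.b.value = z["head_b"]
        return cls(model=None, config=config, space=space, encoder=encoder,
                   center_bn=center_bn, head=head, targets=meta["targets"],
                   history=[], best_epoch=meta["best_epoch"])


# ---------------------------------------------------------------------------
# Zero-shot protocol
# ---------------------------------------------------------------------------

def zero_shot_protocol(dataset: Dataset, holdout_classes: Sequence[str],
                       config: TrainConfig | None = None,
                       include_trained: bool = False,
                       verbose: bool = False) -> pd.DataFrame:
    """Hold classes out of training entirely and score them geometrically.

    The held-out classes' annotations are removed from every protein
    *before* true-path propagation, the model is retrained, and each
    held-out class is scored purely from its axiom-constrained embedding.
    Class-centric AUC is reported on the test split (``auc_test``) and on
    all proteins (``auc_all``).  With ``include_trained=True`` a second,
    uncensored model adds the supervised reference column
    (``auc_trained``, test split).
    """
    import logging
    logger = logging.getLogger(__name__)
    config = config or TrainConfig()
    holdouts = list(holdout_classes)

    defined = {e for _, _, e in dataset.nf.nf2}
    in_axioms = dataset.nf.all_class_ids()
    for c in holdouts:
        if c not in in_axioms:
            logger.warning(
                "held-out class %s has no axiom support; its prediction "
                "will rely on the hierarchy only", c)

    censored = dataset.raw_annotations.copy()
    for terms in censored.annotations.values():
        terms.difference_update(holdouts)
    censored_prop = propagate(censored, dataset.closure)
    truth = propagate(dataset.raw_annotations, dataset.closure)

    model = FunctionPredictionModel.from_dataset(
        dataset, model_type="elembed", exclude_targets=holdouts,
        annotations=censored_prop)
    res = model.fit(config, verbose=verbose)

    trained_res = None
    if include_trained:
        trained = FunctionPredictionModel.from_dataset(
            dataset, model_type="elembed", annotations=truth)
        trained_res = trained.fit(config, verbose=verbose)

    test_ids = dataset.ids_in("test")
    all_ids = list(dataset.protein_ids)

    def auc_for(result, ids, cid):
        X = dataset.feature_rows(ids)
        scores = result.predict(X, [cid]).scores[:, 0]
        y = np.array([cid in truth.annotations.get(p, ()) for p in ids])
        if y.all() or not y.any():
            return float("nan")
        from sklearn.metrics import roc_auc_score
        return float(roc_auc_score(y, scores))

    counts = truth.counts()
    rows = []
    for cid in holdouts:
        row = {
            "class_id": cid,
            "n_annotations": counts.get(cid, 0),
            "defined": cid in defined,
            "auc_test": auc_for(res, test_ids, cid),
            "auc_all": auc_for(res, all_ids, cid),
        }
        if trained_res is not None:
            row["auc_trained"] = auc_for(trained_res, test_ids, cid)
        rows.append(row)
    return pd.DataFrame(rows)
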