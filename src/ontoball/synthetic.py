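"""Desk-scale synthetic fixtures with a planted, recoverable signal.

The generator emulates the statistical shape of the real task at toy
scale:

* a rooted subclass DAG of "GO-like" classes over a handful of
  relations, with existential axioms and a configurable number of
  genus/differentia definitions ``C ≡ D ⊓ ∃R.E`` — so that
  normalization produces all four EL normal forms;
* proteins carrying binary feature vectors in which each base class owns
  a small block of characteristic features: a protein annotated with a
  class activates that class's block with high probability, on top of a
  low background activation rate;
* *honest* definitions: a protein is annotated with a defined class
  exactly when the generative process gave it both the genus class and
  the filler class — so recovering a held-out defined class from its
  definition is information-theoretically possible;
* a synthetic all-vs-all hit table in which proteins sharing primary
  (leaf-level) annotations receive high percent identity and bitscore,
  which exercises the DiamondScore baseline and the group splitter.

What this does **not** emulate: real sequence evolution, GO's topology
statistics, or feature co-occurrence beyond class membership.  Defaults
are sized for fast end-to-end training on a single CPU.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
import yaml

from .model import Dataset, ProteinRecord
from .ontology import (AnnotationSet, Ontology, OntologyClass, RawAxiom,
                       Relation, normalize, subclass_closure, propagate,
                       write_obo, write_annotations)
from .similarity import HIT_COLUMNS, similarity_split, write_split

__all__ = ["SyntheticSpec", "generate_ontology", "generate_proteins",
           "simulate", "write_features", "read_features"]


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic fixture.

    The defaults define a 60-class ontology (8 of them defined classes)
    over 2 relations, 300 proteins with 200 binary features, a strong
    characteristic-feature signal (inclusion probability 0.9 against a
    2% background rate) and roughly two primary leaf annotations per
    protein.
    """

    n_classes: int = 60
    n_definitions: int = 8
    n_relations: int = 2
    n_existential: int = 6
    max_depth: int = 4
    second_parent_prob: float = 0.15
    n_proteins: int = 300
    vocab_size: int = 200
    features_per_class: int = 3
    inclusion_probability: float = 0.9
    background_rate: float = 0.02
    mean_extra_leaves: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_definitions > self.n_classes:
            raise ValueError("n_definitions cannot exceed n_classes")
        for p in ("inclusion_probability", "background_rate",
                  "second_parent_prob"):
            if not 0.0 <= getattr(self, p) <= 1.0:
                raise ValueError(f"{p} must be a probability")

    @property
    def n_base(self) -> int:
        return self.n_classes - self.n_definitions

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _class_id(i: int) -> str:
    return f"SY:{i:07d}"


def _relation_id(i: int) -> str:
    return f"SR:{i:07d}"


def _feature_id(i: int) -> str:
    return f"FT:{i:05d}"


# ---------------------------------------------------------------------------
# Ontology generation
# ---------------------------------------------------------------------------

def generate_ontology(spec: SyntheticSpec
                      ) -> tuple[Ontology, list[RawAxiom]]:
    """A rooted DAG with existential axioms and honest definitions.

    Base classes form the subclass hierarchy; each defined class sits
    under its genus with an equivalence axiom whose genus and filler are
    internal base classes from different branches, so after
    normalization all four NF lists are non-empty whenever
    ``n_definitions >= 1``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_base < spec.max_depth + 1:
        raise ValueError("infeasible spec: depth exceeds class budget")

    ontology = Ontology()
    axioms: list[RawAxiom] = []
    depth: dict[str, int] = {}

    root = _class_id(1)
    ontology.add_class(OntologyClass(root, "root", "synthetic"))
    depth[root] = 0
    base_ids = [root]
    for i in range(2, spec.n_base + 1):
        cid = _class_id(i)
        eligible = [b for b in base_ids if depth[b] < spec.max_depth]
        parent = eligible[rng.integers(len(eligible))]
        ontology.add_class(OntologyClass(cid, f"class {i}", "synthetic"))
        depth[cid] = depth[parent] + 1
        axioms.append(RawAxiom("subclass", (cid, parent)))
        others = [b for b in base_ids if b != parent and depth[b] < spec.max_depth]
        if others and rng.random() < spec.second_parent_prob:
            second = others[rng.integers(len(others))]
            axioms.append(RawAxiom("subclass", (cid, second)))
        base_ids.append(cid)

    relations = [_relation_id(i + 1) for i in range(spec.n_relations)]
    for rid in relations:
        ontology.add_relation(Relation(rid, f"relation {rid}"))

    non_root = base_ids[1:]
    for _ in range(spec.n_existential):
        c = non_root[rng.integers(len(non_root))]
        d = non_root[rng.integers(len(non_root))]
        while d == c:
            d = non_root[rng.integers(len(non_root))]
        r = relations[rng.integers(len(relations))]
        ax = RawAxiom("existential_subclass", (c, r, d))
        if ax not in axioms:
            axioms.append(ax)

    # definitions: genus and filler are internal classes (depth 1-2) from
    # different branches, never related by subclass — the conjunction
    # D ⊓ E is then genuinely more specific than either conjunct.
    closure = subclass_closure(normalize(axioms), classes=base_ids)
    internal = [b for b in base_ids if 1 <= depth[b] <= 2]
    pairs = [(d, e) for d in internal for e in internal
             if d != e and d not in closure[e] and e not in closure[d]]
    if spec.n_definitions > 0 and not pairs:
        raise ValueError("infeasible spec: no independent genus/filler pair")
    order = rng.permutation(len(pairs))
    for k in range(spec.n_definitions):
        d, e = pairs[order[k % len(pairs)]]
        cid = _class_id(spec.n_base + 1 + k)
        r = relations[k % len(relations)]
        ontology.add_class(OntologyClass(cid, f"defined class {k}", "synthetic"))
        depth[cid] = depth[d] + 1
        axioms.append(RawAxiom("intersection_equivalence", (cid, d, r, e)))
    return ontology, axioms


# ---------------------------------------------------------------------------
# Protein generation
# ---------------------------------------------------------------------------

def generate_proteins(spec: SyntheticSpec, ontology: Ontology,
                      axioms: list[RawAxiom]
                      ) -> tuple[list[ProteinRecord], AnnotationSet,
                                 pd.DataFrame]:
    """Proteins with planted feature signal, plus a synthetic hit table.

    Returns propagated records, the raw (pre-propagation) annotation
    set, and the 12-column similarity hits.  Uses an rng derived from
    ``spec.seed`` (offset so ontology and protein draws are independent).
    """
    if spec.n_proteins <= 0:
        raise ValueError("zero proteins requested")
    rng = np.random.default_rng(spec.seed + 1_000_003)
    nf = normalize(axioms)
    closure = subclass_closure(nf, classes=list(ontology.classes))

    subclass_children: dict[str, int] = {}
    for ax in axioms:
        if ax.form == "subclass":
            subclass_children[ax.operands[1]] = \
                subclass_children.get(ax.operands[1], 0) + 1
    definitions = [ax.operands for ax in axioms
                   if ax.form == "intersection_equivalence"]
    defined_ids = {c for c, _, _, _ in definitions}
    base_ids = [c for c in ontology.classes if c not in defined_ids]
    leaves = [c for c in base_ids if subclass_children.get(c, 0) == 0]

    if spec.n_base * spec.features_per_class > spec.vocab_size:
        raise ValueError("vocabulary too small for the per-class blocks")
    blocks = {cid: list(range(i * spec.features_per_class,
                              (i + 1) * spec.features_per_class))
              for i, cid in enumerate(base_ids)}

    records: list[ProteinRecord] = []
    raw: dict[str, set[str]] = {}
    primaries: list[set[str]] = []
    for i in range(spec.n_proteins):
        pid = f"PROT{i:05d}"
        k = min(1 + rng.poisson(spec.mean_extra_leaves), len(leaves))
        primary = set(np.array(leaves)[rng.choice(len(leaves), k,
                                                  replace=False)])
        ann: set[str] = set()
        for leaf in primary:
            ann |= closure[leaf]
        raw_ann = set(primary)
        for c, d, _, e in definitions:
            if d in ann and e in ann:
                ann |= closure[c]
                raw_ann.add(c)
        # characteristic features fire at the inclusion rate, every other
        # feature at the background rate; equal rates mean zero signal
        p_on = np.full(spec.vocab_size, spec.background_rate)
        for cls in ann:
            for f in blocks.get(cls, ()):
                p_on[f] = spec.inclusion_probability
        x = (rng.random(spec.vocab_size) < p_on).astype(np.uint8)
        records.append(ProteinRecord(pid, x, ann))
        raw[pid] = raw_ann
        primaries.append(primary)

    hits = _hit_table(records, primaries, rng)
    return records, AnnotationSet(raw, propagated=False), hits


def _hit_table(records, primaries, rng) -> pd.DataFrame:
    """Pairwise hits with identity proportional to shared primary leaves."""
    rows = []
    n = len(records)
    for i in range(n):
        rows.append((records[i].id, records[i].id, 100.0, 100, 0, 0,
                     1, 100, 1, 100, 1e-50, 200.0))
        for j in range(i + 1, n):
            inter = len(primaries[i] & primaries[j])
            if inter == 0:
                continue
            union = len(primaries[i] | primaries[j])
            sim = inter / union
            pident = 100.0 * sim * (0.85 + 0.15 * rng.random())
            if pident < 30.0:
                continue
            bitscore = round(2.0 * pident * (1.0 + 0.05 * rng.random()), 1)
            evalue = 10.0 ** (-bitscore / 10.0)
            for q, s in ((i, j), (j, i)):
                rows.append((records[q].id, records[s].id, round(pident, 1),
                             100, 0, 0, 1, 100, 1, 100, evalue, bitscore))
    return pd.DataFrame(rows, columns=list(HIT_COLUMNS))


# ---------------------------------------------------------------------------
# Feature-table format
# ---------------------------------------------------------------------------

def write_features(path, records: list[ProteinRecord], vocab_size: int):
    """``protein_id<TAB>FT:...;FT:...`` with a vocab-size header line."""
    with open(path, "w") as fh:
        fh.write(f"#vocab_size={vocab_size}\n")
        for rec in records:
            on = ";".join(_feature_id(i) for i in np.flatnonzero(rec.features))
            fh.write(f"{rec.id}\t{on}\n")


def read_features(path) -> tuple[list[str], np.ndarray]:
    ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#vocab_size="):
            raise ValueError("feature table must start with #vocab_size=")
        vocab = int(header.split("=", 1)[1])
        for line in fh:
            pid, _, feats = line.rstrip("\n").partition("\t")
            x = np.zeros(vocab, dtype=np.uint8)
            for tok in filter(None, feats.split(";")):
                x[int(tok.split(":")[1])] = 1
            ids.append(pid)
            rows.append(x)
    return ids, np.stack(rows) if rows else np.zeros((0, vocab), np.uint8)


# ---------------------------------------------------------------------------
# End-to-end fixture assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticFixture:
    """All generated artifacts plus the assembled :class:`Dataset`."""

    spec: SyntheticSpec
    ontology: Ontology
    axioms: list[RawAxiom]
    records: list[ProteinRecord]
    dataset: Dataset = field(repr=False, default=None)
    hits: pd.DataFrame = field(repr=False, default=None)

    @property
    def definitions(self) -> list[tuple]:
        return [ax.operands for ax in self.axioms
                if ax.form == "intersection_equivalence"]


def simulate(spec: SyntheticSpec | None = None,
             outdir: str | pathlib.Path | None = None) -> SyntheticFixture:
    """Generate the full fixture and optionally write it to disk.

    Writes ``ontology.obo``, ``annotations.tsv`` (raw, experimental
    evidence), ``features.tsv``, ``hits.tsv`` and ``spec.yaml`` — the
    exact formats the rest of the package consumes.
    """
    spec = spec or SyntheticSpec()
    ontology, axioms = generate_ontology(spec)
    records, raw, hits = generate_proteins(spec, ontology, axioms)
    nf = normalize(axioms)
    closure = subclass_closure(nf, classes=list(ontology.classes))
    assignment = similarity_split([r.id for r in records], hits,
                                  seed=spec.seed)
    for rec in records:
        rec.group_id = assignment.group[rec.id]
    dataset = Dataset(
        protein_ids=[r.id for r in records],
        features=np.stack([r.features for r in records]),
        raw_annotations=raw,
        nf=nf,
        closure=closure,
        split=assignment.split,
    )
    fixture = SyntheticFixture(spec, ontology, axioms, records,
                               dataset=dataset, hits=hits)
    if outdir is not None:
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_obo(out / "ontology.obo", ontology, axioms)
        write_annotations(out / "annotations.tsv", raw)
        write_features(out / "features.tsv", records, spec.vocab_size)
        hits.to_csv(out / "hits.tsv", sep="\t", header=False, index=False)
        spec.to_yaml(out / "spec.yaml")
        write_split(out / "split.tsv", assignment, order=dataset.protein_ids)
    return fixture
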