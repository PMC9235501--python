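"""Ontology handling: OBO parsing, EL axiom normalization, hierarchy.

The Gene Ontology (and the toy ontologies generated by
:mod:`ontoball.synthetic`) is consumed as OBO ``[Term]`` stanzas.  Three
axiom shapes are ingested:

* plain subclass axioms ``C SubClassOf D`` (``is_a`` lines),
* existential subclass axioms ``C SubClassOf R some D``
  (``relationship`` lines), and
* definition (equivalence) axioms ``C EquivalentTo D and (R some E)``
  (paired ``intersection_of`` lines) — the genus/differentia definitions
  that make zero-shot prediction possible.

These are normalized into the four EL normal forms

* NF1: ``C ⊑ D``
* NF2: ``C ⊓ D ⊑ E``
* NF3: ``C ⊑ ∃R.D``
* NF4: ``∃R.C ⊑ D``

by rewriting each equivalence ``C ≡ D ⊓ ∃R.E`` into the four entries
``C ⊑ D`` (NF1), ``C ⊑ ∃R.E`` (NF3), ``∃R.E ⊑ X`` (NF4) and
``D ⊓ X ⊑ C`` (NF2), where ``X`` is a fresh class naming the existential
restriction.  The rewrite preserves entailment in both directions; the
test suite verifies this with a brute-force finite-interpretation
checker.

The module also owns the subclass hierarchy (ancestor closure), the
true-path-rule propagation of protein annotations, and information
content used by the Smin evaluation metric.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

#: Relation id reserved for the protein -> function association.
HAS_FUNCTION = "hasFunction"

#: Experimental-evidence whitelist applied when reading annotation tables.
DEFAULT_EVIDENCE_CODES = frozenset(
    ["EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "IC",
     "HTP", "HDA", "HMP", "HGI", "HEP"]
)

NAMESPACES = ("molecular_function", "biological_process",
              "cellular_component", "synthetic")

_KNOWN_TAGS = {"id", "name", "namespace", "is_a", "relationship",
               "intersection_of", "is_obsolete"}


class OboParseError(ValueError):
    """Raised for malformed OBO input, naming the offending line."""


@dataclass(frozen=True)
class OntologyClass:
    id: str
    name: str = ""
    namespace: str = "synthetic"
    obsolete: bool = False


@dataclass(frozen=True)
class Relation:
    id: str
    name: str = ""


@dataclass(frozen=True)
class RawAxiom:
    """One of the three ingested axiom shapes.

    ``form``:
      * ``subclass``: operands (C, D) for C ⊑ D
      * ``existential_subclass``: operands (C, R, D) for C ⊑ ∃R.D
      * ``intersection_equivalence``: operands (C, D, R, E) for C ≡ D ⊓ ∃R.E
    """

    form: str
    operands: tuple

    def __post_init__(self):
        arity = {"subclass": 2, "existential_subclass": 3,
                 "intersection_equivalence": 4}
        if self.form not in arity:
            raise ValueError(f"unknown axiom form {self.form!r}")
        if len(self.operands) != arity[self.form]:
            raise ValueError(
                f"{self.form} axiom needs {arity[self.form]} operands, "
                f"got {self.operands!r}")


@dataclass
class Ontology:
    """Classes and relations; axioms are carried separately as RawAxioms."""

    classes: dict[str, OntologyClass] = field(default_factory=dict)
    relations: dict[str, Relation] = field(default_factory=dict)

    def __post_init__(self):
        self.relations.setdefault(HAS_FUNCTION, Relation(HAS_FUNCTION, "has function"))

    def add_class(self, cls: OntologyClass):
        if cls.id in self.classes:
            raise ValueError(f"duplicate class id {cls.id}")
        self.classes[cls.id] = cls

    def add_relation(self, rel: Relation):
        self.relations.setdefault(rel.id, rel)

    @property
    def active_class_ids(self) -> list[str]:
        """Non-obsolete class ids, in insertion order."""
        return [c.id for c in self.classes.values() if not c.obsolete]

    def namespace_classes(self, namespace: str) -> list[str]:
        return [c.id for c in self.classes.values()
                if not c.obsolete and c.namespace == namespace]


@dataclass
class NormalizedAxiomSet:
    """The four EL normal-form axiom lists produced by :func:`normalize`.

    Tuple layouts: nf1 ``(C, D)``; nf2 ``(C, D, E)`` for C ⊓ D ⊑ E;
    nf3 ``(C, R, D)`` for C ⊑ ∃R.D; nf4 ``(R, C, D)`` for ∃R.C ⊑ D.
    """

    nf1: list[tuple] = field(default_factory=list)
    nf2: list[tuple] = field(default_factory=list)
    nf3: list[tuple] = field(default_factory=list)
    nf4: list[tuple] = field(default_factory=list)
    fresh_classes: list[str] = field(default_factory=list)

    def all_class_ids(self) -> set[str]:
        ids = set()
        for c, d in self.nf1:
            ids.update((c, d))
        for c, d, e in self.nf2:
            ids.update((c, d, e))
        for c, _, d in self.nf3:
            ids.update((c, d))
        for _, c, d in self.nf4:
            ids.update((c, d))
        return ids

    def all_relation_ids(self) -> set[str]:
        return {r for _, r, _ in self.nf3} | {r for r, _, _ in self.nf4}


@dataclass
class AnnotationSet:
    """Mapping protein id -> set of class ids, with a propagation flag."""

    annotations: dict[str, set[str]]
    propagated: bool = False

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for terms in self.annotations.values():
            for t in terms:
                out[t] = out.get(t, 0) + 1
        return out

    def copy(self) -> "AnnotationSet":
        return AnnotationSet({p: set(t) for p, t in self.annotations.items()},
                             self.propagated)


# ---------------------------------------------------------------------------
# OBO parsing
# ---------------------------------------------------------------------------

def _strip_comment(value: str) -> str:
    # OBO trailing comments: "GO:0005488 ! binding"
    return value.split(" ! ")[0].strip()


def read_obo(path) -> tuple[Ontology, list[RawAxiom]]:
    """Parse OBO ``[Term]``/``[Typedef]`` stanzas into an Ontology + axioms.

    Only ``id``, ``name``, ``namespace``, ``is_a``, ``relationship``,
    ``intersection_of`` and ``is_obsolete`` tags are interpreted; other
    tags are ignored (their count is logged).  Axioms touching an
    obsolete class, and ``is_a`` edges crossing namespaces, are dropped
    with a logged count.  Unresolved class references raise.
    """
    ontology = Ontology()
    axioms: list[RawAxiom] = []
    pending: list[tuple] = []  # (kind, payload, lineno) resolved after parse
    ignored_tags = 0

    stanza_type = None
    term: dict | None = None
    term_line = 0

    def flush():
        nonlocal term
        if stanza_type == "Term" and term is not None:
            if "id" not in term:
                raise OboParseError(
                    f"line {term_line}: [Term] stanza without an id tag")
            cid = term["id"]
            ontology.add_class(OntologyClass(
                id=cid, name=term.get("name", ""),
                namespace=term.get("namespace", "synthetic"),
                obsolete=term.get("obsolete", False)))
            ix = term.get("intersection_of", [])
            if ix:
                genus = [g for g in ix if len(g) == 1]
                diff = [g for g in ix if len(g) == 2]
                if len(ix) != 2 or len(genus) != 1 or len(diff) != 1:
                    raise OboParseError(
                        f"line {term_line}: term {cid}: only definitions of "
                        f"the shape 'genus and (relation some filler)' are "
                        f"supported; got {len(ix)} intersection_of lines")
                d, (r, e) = genus[0][0], diff[0]
                pending.append(("equiv", (cid, d, r, e), term_line))
        elif stanza_type == "Typedef" and term is not None and "id" in term:
            ontology.add_relation(Relation(term["id"], term.get("name", "")))
        term = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("!"):
                continue
            if line.startswith("["):
                flush()
                stanza_type = line.strip("[]")
                term = {} if stanza_type in ("Term", "Typedef") else None
                term_line = lineno
                continue
            if ":" not in line:
                raise OboParseError(f"line {lineno}: expected 'tag: value', got {line!r}")
            tag, _, value = line.partition(":")
            tag = tag.strip()
            value = _strip_comment(value)
            if term is None:  # header or unsupported stanza
                continue
            if tag not in _KNOWN_TAGS:
                ignored_tags += 1
                continue
            if tag == "is_obsolete":
                term["obsolete"] = value.lower() == "true"
            elif tag == "is_a":
                pending.append(("is_a", (term.get("id"), value), lineno))
                term.setdefault("_edges", []).append(value)
            elif tag == "relationship":
                parts = value.split()
                if len(parts) != 2:
                    raise OboParseError(
                        f"line {lineno}: relationship needs 'REL TARGET', got {value!r}")
                pending.append(("rel", (term.get("id"), parts[0], parts[1]), lineno))
            elif tag == "intersection_of":
                parts = tuple(value.split())
                if len(parts) not in (1, 2):
                    raise OboParseError(
                        f"line {lineno}: unsupported intersection_of line {value!r}")
                term.setdefault("intersection_of", []).append(parts)
            else:
                term[tag] = value
        flush()

    # is_a/relationship lines were recorded before the stanza id was
    # necessarily known; re-resolve subjects now.
    def subject_of(entry):
        kind, payload, lineno = entry
        if payload[0] is None:
            raise OboParseError(f"line {lineno}: {kind} line precedes the id tag")
        return payload[0]

    unresolved = set()
    dropped_obsolete = 0
    dropped_cross_ns = 0
    for kind, payload, lineno in pending:
        subject_of((kind, payload, lineno))
        if kind == "is_a":
            c, d = payload
            for x in (c, d):
                if x not in ontology.classes:
                    unresolved.add(x)
            if unresolved & {c, d}:
                continue
            if ontology.classes[c].obsolete or ontology.classes[d].obsolete:
                dropped_obsolete += 1
                continue
            if ontology.classes[c].namespace != ontology.classes[d].namespace:
                dropped_cross_ns += 1
                continue
            axioms.append(RawAxiom("subclass", (c, d)))
        elif kind == "rel":
            c, r, d = payload
            for x in (c, d):
                if x not in ontology.classes:
                    unresolved.add(x)
            if unresolved & {c, d}:
                continue
            if ontology.classes[c].obsolete or ontology.classes[d].obsolete:
                dropped_obsolete += 1
                continue
            ontology.add_relation(Relation(r))
            axioms.append(RawAxiom("existential_subclass", (c, r, d)))
        else:  # equivalence
            c, d, r, e = payload
            for x in (c, d, e):
                if x not in ontology.classes:
                    unresolved.add(x)
            if unresolved & {c, d, e}:
                continue
            if any(ontology.classes[x].obsolete for x in (c, d, e)):
                dropped_obsolete += 1
                continue
            ontology.add_relation(Relation(r))
            axioms.append(RawAxiom("intersection_equivalence", (c, d, r, e)))

    if unresolved:
        raise OboParseError(
            "unresolved class references: " + ", ".join(sorted(unresolved)))
    if ignored_tags:
        logger.info("read_obo: ignored %d unknown tag lines", ignored_tags)
    if dropped_obsolete:
        logger.warning("read_obo: dropped %d axioms touching obsolete classes",
                       dropped_obsolete)
    if dropped_cross_ns:
        logger.warning("read_obo: dropped %d cross-namespace is_a edges",
                       dropped_cross_ns)
    return ontology, axioms


def write_obo(path, ontology: Ontology, axioms: Iterable[RawAxiom]):
    """Serialize an ontology and its raw axioms as OBO [Term] stanzas."""
    by_class: dict[str, dict] = {cid: {"is_a": [], "rel": [], "equiv": None}
                                 for cid in ontology.classes}
    for ax in axioms:
        if ax.form == "subclass":
            by_class[ax.operands[0]]["is_a"].append(ax.operands[1])
        elif ax.form == "existential_subclass":
            c, r, d = ax.operands
            by_class[c]["rel"].append((r, d))
        else:
            c, d, r, e = ax.operands
            by_class[c]["equiv"] = (d, r, e)
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: ontoball/synthetic\n")
        for cid, cls in ontology.classes.items():
            fh.write(f"\n[Term]\nid: {cid}\nname: {cls.name}\n")
            fh.write(f"namespace: {cls.namespace}\n")
            entry = by_class[cid]
            for parent in entry["is_a"]:
                fh.write(f"is_a: {parent}\n")
            if entry["equiv"] is not None:
                d, r, e = entry["equiv"]
                fh.write(f"intersection_of: {d}\n")
                fh.write(f"intersection_of: {r} {e}\n")
            for r, d in entry["rel"]:
                fh.write(f"relationship: {r} {d}\n")
            if cls.obsolete:
                fh.write("is_obsolete: true\n")
        for rid, rel in ontology.relations.items():
            fh.write(f"\n[Typedef]\nid: {rid}\nname: {rel.name}\n")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize(axioms: Iterable[RawAxiom]) -> NormalizedAxiomSet:
    """Rewrite raw axioms into the four EL normal forms.

    Fresh classes introduced for existential fillers of equivalences are
    named ``NFX:<k>`` with ``k`` a counter over the canonically sorted
    input axioms, so the output is reproducible run-to-run.
    """
    ordered = sorted(set(axioms), key=lambda a: (a.form, a.operands))
    out = NormalizedAxiomSet()
    seen = {"nf1": set(), "nf2": set(), "nf3": set(), "nf4": set()}

    def _add(lst_name: str, entry: tuple):
        if entry not in seen[lst_name]:
            seen[lst_name].add(entry)
            getattr(out, lst_name).append(entry)

    counter = 0
    for ax in ordered:
        if ax.form == "subclass":
            _add("nf1", ax.operands)
        elif ax.form == "existential_subclass":
            _add("nf3", ax.operands)
        else:
            c, d, r, e = ax.operands
            fresh = f"NFX:{counter}"
            counter += 1
            out.fresh_classes.append(fresh)
            _add("nf1", (c, d))          # C ⊑ D
            _add("nf3", (c, r, e))       # C ⊑ ∃R.E
            _add("nf4", (r, e, fresh))   # ∃R.E ⊑ X
            _add("nf2", (d, fresh, c))   # D ⊓ X ⊑ C
    return out


_NF_COLUMNS = ("form", "c", "d", "e", "r")


def write_normalized(path, nf: NormalizedAxiomSet):
    """Export a NormalizedAxiomSet as TSV (columns form, c, d, e, r)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_NF_COLUMNS) + "\n")
        for c, d in nf.nf1:
            fh.write(f"nf1\t{c}\t{d}\t\t\n")
        for c, d, e in nf.nf2:
            fh.write(f"nf2\t{c}\t{d}\t{e}\t\n")
        for c, r, d in nf.nf3:
            fh.write(f"nf3\t{c}\t{d}\t\t{r}\n")
        for r, c, d in nf.nf4:
            fh.write(f"nf4\t{c}\t{d}\t\t{r}\n")
        for x in nf.fresh_classes:
            fh.write(f"fresh\t{x}\t\t\t\n")


def read_normalized(path) -> NormalizedAxiomSet:
    nf = NormalizedAxiomSet()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _NF_COLUMNS:
            raise ValueError(f"unexpected normalized-axiom header {header}")
        for line in fh:
            form, c, d, e, r = line.rstrip("\n").split("\t")
            if form == "nf1":
                nf.nf1.append((c, d))
            elif form == "nf2":
                nf.nf2.append((c, d, e))
            elif form == "nf3":
                nf.nf3.append((c, r, d))
            elif form == "nf4":
                nf.nf4.append((r, c, d))
            elif form == "fresh":
                nf.fresh_classes.append(c)
            else:
                raise ValueError(f"unknown normal form {form!r}")
    return nf


# ---------------------------------------------------------------------------
# Hierarchy: closure, propagation, information content
# ---------------------------------------------------------------------------

def subclass_graph(nf: NormalizedAxiomSet) -> "nx.DiGraph":
    """Child -> parent digraph of the NF1 edges."""
    g = nx.DiGraph()
    g.add_edges_from(nf.nf1)
    return g


def subclass_closure(nf: NormalizedAxiomSet,
                     classes: Iterable[str] | None = None) -> dict[str, set[str]]:
    """Reflexive-transitive ancestor map of the NF1 subclass edges.

    Fresh (normalization-generated) classes are dropped from the ancestor
    sets reported for real classes.  A cycle among real classes is an
    error (GO's is_a hierarchy is a DAG); one offending cycle is named.
    """
    fresh = set(nf.fresh_classes)
    g = subclass_graph(nf)
    if classes is not None:
        g.add_nodes_from(classes)
    real = g.subgraph([n for n in g if n not in fresh])
    if not nx.is_directed_acyclic_graph(real):
        cycle = nx.find_cycle(real)
        path = " ⊑ ".join(str(u) for u, _ in cycle) + f" ⊑ {cycle[0][0]}"
        raise ValueError(f"cycle in subclass hierarchy: {path}")
    closure: dict[str, set[str]] = {}
    for node in g:
        anc = nx.descendants(g, node)  # edges point child -> parent
        anc.add(node)
        if node not in fresh:
            anc -= fresh
        closure[node] = anc
    return closure


def direct_parents(nf: NormalizedAxiomSet) -> dict[str, set[str]]:
    """Direct (one-edge) NF1 parents per class, fresh classes excluded."""
    fresh = set(nf.fresh_classes)
    parents: dict[str, set[str]] = {}
    for c, d in nf.nf1:
        if c in fresh or d in fresh:
            continue
        parents.setdefault(c, set()).add(d)
        parents.setdefault(d, set())
    return parents


def propagate(annotations: AnnotationSet,
              closure: Mapping[str, set[str]]) -> AnnotationSet:
    """Close every protein's annotation set under subclass ancestors.

    This is the true-path rule: annotation to a class entails annotation
    to all of its ancestors.  Idempotent; input is not modified.
    """
    out: dict[str, set[str]] = {}
    for pid, terms in annotations.annotations.items():
        acc: set[str] = set()
        for t in terms:
            if t not in closure:
                raise KeyError(
                    f"protein {pid}: class {t} has no hierarchy entry")
            acc |= closure[t]
        out[pid] = acc
    return AnnotationSet(out, propagated=True)


def information_content(annotations: AnnotationSet,
                        closure: Mapping[str, set[str]] | None = None,
                        *,
                        parents: Mapping[str, set[str]] | None = None,
                        mode: str = "conditional",
                        base: float = 2.0,
                        pseudocount: float = 1.0) -> dict[str, float]:
    """Per-class information content over a propagated annotation corpus.

    ``mode="conditional"`` (default) is the CAFA form used by Smin,
    ``IC(c) = -log P(c | parents(c))`` with the parent probability taken
    as the fraction of proteins annotated with *all* direct parents of
    ``c``.  ``mode="marginal"`` gives ``-log P(c)``.  ``base=2`` yields
    bits, ``base=math.e`` nats.  Classes with no annotated proteins fall
    back to ``pseudocount / (denominator + pseudocount)``.
    """
    if not annotations.annotations:
        raise ValueError("empty annotation corpus")
    if not annotations.propagated:
        raise ValueError("annotations must be propagated before computing IC")
    if mode not in ("conditional", "marginal"):
        raise ValueError(f"unknown IC mode {mode!r}")
    if mode == "conditional" and parents is None:
        raise ValueError("conditional IC requires the direct-parents map")

    n_prot = len(annotations.annotations)
    counts = annotations.counts()
    universe = set(counts)
    if parents is not None:
        universe |= set(parents)
    if closure is not None:
        universe |= set(closure)

    ic: dict[str, float] = {}
    log = math.log
    for c in universe:
        num = counts.get(c, 0)
        if mode == "marginal":
            denom = n_prot
        else:
            par = parents.get(c, set())
            if par:
                denom = sum(
                    1 for terms in annotations.annotations.values()
                    if par <= terms)
            else:
                denom = n_prot  # a root: conditional on nothing
        if num > 0 and denom > 0:
            p = num / denom
        else:
            p = pseudocount / (denom + pseudocount) if pseudocount > 0 else None
        if p is None:
            continue  # IC undefined without a pseudocount
        ic[c] = max(0.0, -log(p) / log(base))
    return ic


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

def read_annotations(path,
                     evidence_codes: Iterable[str] | None = DEFAULT_EVIDENCE_CODES
                     ) -> AnnotationSet:
    """Read a ``protein_id<TAB>go_id<TAB>evidence_code`` table.

    Rows whose evidence code is outside the whitelist are skipped (pass
    ``evidence_codes=None`` to keep everything).
    """
    whitelist = None if evidence_codes is None else set(evidence_codes)
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 tab-separated "
                    f"columns, got {len(parts)}")
            pid, go, code = parts
            if whitelist is not None and code not in whitelist:
                continue
            out.setdefault(pid, set()).add(go)
    return AnnotationSet(out, propagated=False)


def write_annotations(path, annotations: AnnotationSet,
                      evidence_code: str = "EXP"):
    with open(path, "w") as fh:
        for pid in sorted(annotations.annotations):
            for go in sorted(annotations.annotations[pid]):
                fh.write(f"{pid}\t{go}\t{evidence_code}\n")
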