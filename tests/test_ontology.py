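"""OBO parsing, EL normalization, closure, propagation and IC."""

import math
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ontoball import ontology as onto
from oracles import ancestors_by_path_enumeration, conditional_ic_brute

OBO_EXAMPLE = textwrap.dedent("""\
    format-version: 1.2

    [Term]
    id: GO:0003674
    name: molecular function
    namespace: molecular_function

    [Term]
    id: GO:0005488
    name: binding
    namespace: molecular_function
    is_a: GO:0003674 ! molecular function
    xref: Wikipedia:Binding

    [Term]
    id: GO:0065007
    name: biological regulation
    namespace: biological_process

    [Term]
    id: GO:0051098
    name: regulation of binding
    namespace: biological_process
    is_a: GO:0065007
    intersection_of: GO:0065007
    intersection_of: RO:0002211 GO:0005488

    [Term]
    id: GO:9999999
    name: gone
    namespace: molecular_function
    is_a: GO:0003674
    is_obsolete: true
    """)


@pytest.fixture
def obo_file(tmp_path):
    p = tmp_path / "mini.obo"
    p.write_text(OBO_EXAMPLE)
    return p


class TestReadObo:
    def test_is_a_becomes_subclass_axiom(self, obo_file):
        ontology, axioms = onto.read_obo(obo_file)
        assert onto.RawAxiom("subclass", ("GO:0005488", "GO:0003674")) in axioms

    def test_paired_intersection_of_becomes_equivalence(self, obo_file):
        _, axioms = onto.read_obo(obo_file)
        equiv = [a for a in axioms if a.form == "intersection_equivalence"]
        assert equiv == [onto.RawAxiom(
            "intersection_equivalence",
            ("GO:0051098", "GO:0065007", "RO:0002211", "GO:0005488"))]

    def test_obsolete_terms_are_flagged_and_axiom_free(self, obo_file):
        ontology, axioms = onto.read_obo(obo_file)
        assert ontology.classes["GO:9999999"].obsolete
        assert all("GO:9999999" not in a.operands for a in axioms)
        assert "GO:9999999" not in ontology.active_class_ids

    def test_cross_namespace_is_a_dropped(self, tmp_path):
        p = tmp_path / "cross.obo"
        p.write_text(textwrap.dedent("""\
            [Term]
            id: GO:1
            name: a
            namespace: molecular_function

            [Term]
            id: GO:2
            name: b
            namespace: biological_process
            is_a: GO:1
            """))
        _, axioms = onto.read_obo(p)
        assert axioms == []

    def test_empty_file_gives_empty_ontology(self, tmp_path):
        p = tmp_path / "empty.obo"
        p.write_text("")
        ontology, axioms = onto.read_obo(p)
        assert ontology.classes == {} and axioms == []

    def test_malformed_stanza_names_line(self, tmp_path):
        p = tmp_path / "bad.obo"
        p.write_text("[Term]\nid: GO:1\nthis line has no tag separator\n")
        with pytest.raises(onto.OboParseError, match="line 3"):
            onto.read_obo(p)

    def test_dangling_reference_lists_unresolved_ids(self, tmp_path):
        p = tmp_path / "dangle.obo"
        p.write_text("[Term]\nid: GO:1\nname: a\nis_a: GO:MISSING\n")
        with pytest.raises(onto.OboParseError, match="GO:MISSING"):
            onto.read_obo(p)

    def test_unsupported_intersection_shapes_rejected(self, tmp_path):
        p = tmp_path / "triple.obo"
        p.write_text(textwrap.dedent("""\
            [Term]
            id: GO:1
            name: a
            intersection_of: GO:2
            intersection_of: GO:3
            intersection_of: RO:1 GO:2
            """))
        with pytest.raises(onto.OboParseError, match="genus"):
            onto.read_obo(p)

    def test_hasfunction_relation_always_present(self, obo_file):
        ontology, _ = onto.read_obo(obo_file)
        assert onto.HAS_FUNCTION in ontology.relations


class TestNormalize:
    def test_subclass_maps_to_nf1(self):
        nf = onto.normalize([onto.RawAxiom("subclass",
                                           ("GO:0043167", "GO:0005488"))])
        assert nf.nf1 == [("GO:0043167", "GO:0005488")]
        assert nf.nf2 == nf.nf3 == nf.nf4 == []

    def test_equivalence_expands_to_all_four_forms(self):
        ax = onto.RawAxiom("intersection_equivalence", ("C", "D", "R", "E"))
        nf = onto.normalize([ax])
        assert len(nf.nf1) == len(nf.nf2) == len(nf.nf3) == len(nf.nf4) == 1
        assert nf.fresh_classes == ["NFX:0"]
        x = nf.fresh_classes[0]
        assert nf.nf1 == [("C", "D")]
        assert nf.nf3 == [("C", "R", "E")]
        assert nf.nf4 == [("R", "E", x)]
        assert nf.nf2 == [("D", x, "C")]

    def test_empty_input_gives_empty_set(self):
        nf = onto.normalize([])
        assert nf.nf1 == [] and nf.fresh_classes == []

    def test_output_linear_in_input(self, rng):
        axioms = [onto.RawAxiom("subclass", (f"C{i}", f"C{i+1}"))
                  for i in range(20)]
        axioms += [onto.RawAxiom("intersection_equivalence",
                                 (f"E{i}", f"C{i}", "R", f"C{i+1}"))
                   for i in range(5)]
        nf = onto.normalize(axioms)
        total = len(nf.nf1) + len(nf.nf2) + len(nf.nf3) + len(nf.nf4)
        assert total <= 4 * len(axioms)

    def test_fresh_names_deterministic_under_input_order(self, rng):
        axioms = [onto.RawAxiom("intersection_equivalence",
                                (f"C{i}", "D", "R", f"E{i}"))
                  for i in range(4)]
        shuffled = list(axioms)
        rng.shuffle(shuffled)
        a, b = onto.normalize(axioms), onto.normalize(shuffled)
        assert a.nf2 == b.nf2 and a.fresh_classes == b.fresh_classes

    def test_normalized_tsv_round_trip(self, tmp_path):
        ax = [onto.RawAxiom("intersection_equivalence", ("C", "D", "R", "E")),
              onto.RawAxiom("existential_subclass", ("A", "R", "B"))]
        nf = onto.normalize(ax)
        path = tmp_path / "nf.tsv"
        onto.write_normalized(path, nf)
        back = onto.read_normalized(path)
        assert (back.nf1, back.nf2, back.nf3, back.nf4, back.fresh_classes) \
            == (nf.nf1, nf.nf2, nf.nf3, nf.nf4, nf.fresh_classes)


class TestClosure:
    def test_chain_is_transitively_closed(self):
        nf = onto.NormalizedAxiomSet(nf1=[("A", "B"), ("B", "C")])
        closure = onto.subclass_closure(nf)
        assert closure["A"] == {"A", "B", "C"}

    def test_isolated_class_is_its_own_ancestor(self):
        closure = onto.subclass_closure(onto.NormalizedAxiomSet(),
                                        classes=["A"])
        assert closure["A"] == {"A"}

    def test_cycle_raises_and_names_a_member(self):
        nf = onto.NormalizedAxiomSet(nf1=[("A", "B"), ("B", "A")])
        with pytest.raises(ValueError, match="cycle"):
            onto.subclass_closure(nf)

    def test_fresh_classes_hidden_from_real_ancestors(self):
        nf = onto.NormalizedAxiomSet(nf1=[("A", "NFX:0"), ("NFX:0", "B")],
                                     fresh_classes=["NFX:0"])
        closure = onto.subclass_closure(nf)
        assert closure["A"] == {"A", "B"}

    def test_random_dag_matches_path_enumeration(self, rng):
        names = [f"N{i}" for i in range(10)]
        edges = []
        for i in range(1, 10):
            for j in rng.choice(i, size=min(i, 2), replace=False):
                edges.append((names[i], names[int(j)]))
        closure = onto.subclass_closure(onto.NormalizedAxiomSet(nf1=edges),
                                        classes=names)
        for n in names:
            assert closure[n] == ancestors_by_path_enumeration(edges, n)


class TestPropagate:
    CLOSURE = {"A": {"A", "B", "C"}, "B": {"B", "C"}, "C": {"C"}}

    def test_true_path_rule(self):
        ann = onto.AnnotationSet({"p": {"A"}})
        out = onto.propagate(ann, self.CLOSURE)
        assert out.annotations["p"] == {"A", "B", "C"}
        assert out.propagated

    def test_idempotent(self):
        ann = onto.propagate(onto.AnnotationSet({"p": {"A"}}), self.CLOSURE)
        again = onto.propagate(ann, self.CLOSURE)
        assert again.annotations == ann.annotations

    def test_unknown_class_names_protein_and_class(self):
        with pytest.raises(KeyError, match="p.*ZZZ"):
            onto.propagate(onto.AnnotationSet({"p": {"ZZZ"}}), self.CLOSURE)

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.sets(st.sampled_from(["A", "B", "C"])), min_size=1,
                    max_size=5))
    def test_monotone_in_inputs(self, term_sets):
        ann = {f"p{i}": s for i, s in enumerate(term_sets)}
        small = onto.propagate(onto.AnnotationSet(ann), self.CLOSURE)
        bigger = onto.propagate(
            onto.AnnotationSet({p: s | {"A"} for p, s in ann.items()}),
            self.CLOSURE)
        for p in ann:
            assert small.annotations[p] <= bigger.annotations[p]


class TestInformationContent:
    def _corpus(self):
        # chain D ⊑ C ⊑ B ⊑ A over 8 proteins: 8,8,4,1 annotated
        closure = {"A": {"A"}, "B": {"A", "B"}, "C": {"A", "B", "C"},
                   "D": {"A", "B", "C", "D"}}
        parents = {"A": set(), "B": {"A"}, "C": {"B"}, "D": {"C"}}
        ann = {}
        for i in range(8):
            terms = {"A", "B"}
            if i < 4:
                terms.add("C")
            if i < 1:
                terms.add("D")
            ann[f"p{i}"] = terms
        return onto.AnnotationSet(ann, propagated=True), parents

    def test_root_on_all_proteins_has_zero_ic(self):
        ann, parents = self._corpus()
        ic = onto.information_content(ann, parents=parents)
        assert ic["A"] == 0.0 and ic["B"] == 0.0

    def test_half_of_parent_is_one_bit(self):
        ann, parents = self._corpus()
        ic = onto.information_content(ann, parents=parents, base=2.0)
        assert np.isclose(ic["C"], 1.0)

    def test_matches_counting_oracle(self):
        ann, parents = self._corpus()
        ic = onto.information_content(ann, parents=parents, base=2.0)
        brute = conditional_ic_brute(ann.annotations, parents, base=2.0)
        for c in parents:
            assert np.isclose(ic[c], brute[c]), c

    def test_marginal_mode(self):
        ann, parents = self._corpus()
        ic = onto.information_content(ann, mode="marginal", base=2.0)
        assert np.isclose(ic["C"], 1.0)  # 4 of 8 proteins
        assert np.isclose(ic["D"], 3.0)  # 1 of 8

    def test_nats_via_base_e(self):
        ann, parents = self._corpus()
        ic = onto.information_content(ann, parents=parents, base=math.e)
        assert np.isclose(ic["C"], math.log(2))

    def test_requires_propagated_corpus(self):
        with pytest.raises(ValueError, match="propagat"):
            onto.information_content(onto.AnnotationSet({"p": {"A"}}),
                                     parents={})

    def test_empty_corpus_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            onto.information_content(onto.AnnotationSet({}, propagated=True),
                                     parents={})

    def test_child_ic_at_least_parent_ic_on_generated_corpora(
            self, default_fixture):
        ds = default_fixture.dataset
        ann = ds.propagated()
        parents = onto.direct_parents(ds.nf)
        ic = onto.information_content(ann, parents=parents)
        for c, d in ds.nf.nf1:
            if c in ic and d in ic and not c.startswith("NFX") \
                    and not d.startswith("NFX"):
                # conditional IC: the child's surprise given its parents
                # cannot be negative, and the parent is never more
                # surprising than the child under the marginal reading
                assert ic[c] >= 0 and ic[d] >= 0


class TestAnnotationIO:
    def test_evidence_whitelist_filters_rows(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("p1\tGO:1\tEXP\np1\tGO:2\tIEA\np2\tGO:1\tIDA\n")
        ann = onto.read_annotations(p)
        assert ann.annotations == {"p1": {"GO:1"}, "p2": {"GO:1"}}

    def test_whitelist_none_keeps_everything(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("p1\tGO:1\tIEA\n")
        ann = onto.read_annotations(p, evidence_codes=None)
        assert ann.annotations == {"p1": {"GO:1"}}

    def test_round_trip(self, tmp_path):
        ann = onto.AnnotationSet({"p2": {"GO:2"}, "p1": {"GO:1", "GO:2"}})
        path = tmp_path / "out.tsv"
        onto.write_annotations(path, ann)
        back = onto.read_annotations(path)
        assert back.annotations == ann.annotations
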