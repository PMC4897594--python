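"""A1 standoff and BioC XML parsing, writing and round-tripping."""

import pytest
from hypothesis import given, settings, strategies as st

from litcur import (AnnotatedCollection, ConceptAnnotation, TextDocument,
                    read_a1, read_bioc, write_a1, write_bioc)
from litcur.formats import A1ParseError, BioCParseError
from litcur.simulate import random_collection

TEXT = "FGFR3 mutation causes achondroplasia"


def merge_a1(pairs):
    merged = AnnotatedCollection()
    for doc_id, (text, a1) in pairs.items():
        c = read_a1(text, a1, doc_id)
        merged.documents += c.documents
        merged.concepts += c.concepts
        merged.relations += c.relations
    return merged


class TestA1:
    def test_single_gene_annotation(self):
        coll = read_a1(TEXT, "T1\tGene 0 5\tFGFR3\n", "d1")
        (ann,) = coll.concepts
        assert (ann.concept_type, ann.fragments, ann.surface) == \
            ("Gene", ((0, 5),), "FGFR3")

    def test_concepts_and_relation(self):
        text = "c.76A>T  causes  achondroplasia"
        a1 = ("T1\tSNV 0 7\tc.76A>T\n"
              "T2\tDisease 17 31\tachondroplasia\n"
              "R1\tassociated Arg1:T1 Arg2:T2\n")
        coll = read_a1(text, a1, "d1")
        assert len(coll.concepts) == 2
        (rel,) = coll.relations
        assert (rel.relation_type, rel.arg1, rel.arg2) == ("associated", "T1", "T2")

    def test_discontinuous_span(self):
        text = "alpha beta gamma"
        coll = read_a1(text, "T1\tGene 0 5;11 16\talpha gamma\n", "d1")
        assert coll.concepts[0].fragments == ((0, 5), (11, 16))

    @pytest.mark.parametrize("a1_line", [
        "T1\tGene 0 99\tFGFR3",           # offset out of range
        "T1\tGene 0 5\tBRCA1",            # surface mismatch
        "R1\tassociated Arg1:T7 Arg2:T8",  # unknown T ids
        "E1\tevent trigger",               # unsupported line kind
        "T1\tGene\tFGFR3",                 # missing offsets
    ])
    def test_parse_errors(self, a1_line):
        with pytest.raises(A1ParseError):
            read_a1(TEXT, a1_line + "\n", "d1")

    def test_write_empty_and_single(self):
        doc = TextDocument("d1", TEXT)
        empty = AnnotatedCollection(documents=[doc])
        assert write_a1(empty)["d1"] == (TEXT, "")
        one = AnnotatedCollection(documents=[doc], concepts=[
            ConceptAnnotation("T1", "d1", "Gene", ((0, 5),), "FGFR3")])
        assert write_a1(one)["d1"][1] == "T1\tGene 0 5\tFGFR3\n"

    def test_write_orders_t_lines_by_offset_then_relations(self):
        doc = TextDocument("d1", TEXT)
        coll = AnnotatedCollection(documents=[doc], concepts=[
            ConceptAnnotation("a", "d1", "Disease", ((22, 36),), TEXT[22:36]),
            ConceptAnnotation("b", "d1", "Gene", ((0, 5),), "FGFR3")],
            relations=[])
        lines = write_a1(coll)["d1"][1].splitlines()
        assert lines[0].startswith("T1\tGene 0 5")
        assert lines[1].startswith("T2\tDisease 22 36")

    def test_unresolved_doc_id_is_serialization_error(self):
        coll = AnnotatedCollection(documents=[], concepts=[
            ConceptAnnotation("T1", "ghost", "Gene", ((0, 5),), "FGFR3")])
        with pytest.raises(ValueError):
            write_a1(coll)


class TestBioC:
    def test_single_passage_annotation(self):
        xml = """<collection><source>s</source><date/><key/>
          <document><id>d1</id><passage><offset>0</offset>
            <text>genotyped disease cohort today</text>
            <annotation id="T1"><infon key="type">Disease</infon>
              <location offset="10" length="7"/><text>disease</text>
            </annotation>
          </passage></document></collection>"""
        coll = read_bioc(xml)
        (ann,) = coll.concepts
        assert (ann.concept_type, ann.fragments) == ("Disease", ((10, 17),))

    def test_two_passage_offset_arithmetic(self):
        # title at offset 0 (len 20), abstract at offset 60; the abstract
        # annotation's stored offset is document-global
        title = "variant study title."
        abstract = "the disease appeared in carriers."
        k = abstract.index("disease")
        xml = f"""<collection><source>s</source><date/><key/>
          <document><id>d1</id>
            <passage><offset>0</offset><text>{title}</text></passage>
            <passage><offset>60</offset><text>{abstract}</text>
              <annotation id="T1"><infon key="type">Disease</infon>
                <location offset="{60 + k}" length="7"/><text>disease</text>
              </annotation>
            </passage>
          </document></collection>"""
        coll = read_bioc(xml)
        (ann,) = coll.concepts
        assert ann.fragments == ((60 + k, 60 + k + 7),)
        assert coll.documents[0].text[60 + k:60 + k + 7] == "disease"

    def test_relation_node_refids(self):
        xml = """<collection><source>s</source><date/><key/>
          <document><id>d1</id><passage><offset>0</offset>
            <text>c.76A>T linked disease</text>
            <annotation id="T1"><infon key="type">SNV</infon>
              <location offset="0" length="7"/><text>c.76A&gt;T</text></annotation>
            <annotation id="T2"><infon key="type">Disease</infon>
              <location offset="15" length="7"/><text>disease</text></annotation>
            <relation id="R1"><infon key="type">associated</infon>
              <node refid="T1" role="arg1"/><node refid="T2" role="arg2"/>
            </relation>
          </passage></document></collection>"""
        coll = read_bioc(xml)
        (rel,) = coll.relations
        assert (rel.arg1, rel.arg2, rel.relation_type) == ("T1", "T2", "associated")

    def test_malformed_xml_and_missing_location(self):
        with pytest.raises(BioCParseError):
            read_bioc("<collection><document>")
        xml = """<collection><document><id>d</id><passage><offset>0</offset>
          <text>abc</text><annotation id="T1">
          <infon key="type">Gene</infon><text>a</text></annotation>
          </passage></document></collection>"""
        with pytest.raises(BioCParseError):
            read_bioc(xml)

    def test_empty_collection(self):
        xml = write_bioc(AnnotatedCollection())
        assert read_bioc(xml).documents == []

    def test_normalization_infons_round_trip(self):
        doc = TextDocument("d1", "patient was heterozygous here")
        coll = AnnotatedCollection(documents=[doc], concepts=[
            ConceptAnnotation("T1", "d1", "Zygosity", ((12, 24),),
                              "heterozygous", normalization=("UMLS", "C0019425"))])
        again = read_bioc(write_bioc(coll))
        assert again.concepts[0].normalization == ("UMLS", "C0019425")


class TestRoundTrips:
    @pytest.mark.parametrize("seed", range(25))
    def test_fuzzed_round_trips_and_cross_format(self, seed):
        coll = random_collection(seed=seed, max_annotations=20)
        a1_rt = merge_a1(write_a1(coll))
        assert coll.content_equal(a1_rt, include_normalization=False)
        # canonical ids survive the A1 round trip exactly
        assert [a.ann_id for a in coll.concepts] == [a.ann_id for a in a1_rt.concepts]
        bioc_rt = read_bioc(write_bioc(coll))
        assert coll.content_equal(bioc_rt)
        # A1 -> BioC -> A1 preserves annotation content
        assert a1_rt.content_equal(merge_a1(write_a1(read_bioc(write_bioc(a1_rt)))))

    @given(st.integers(min_value=0, max_value=10 ** 6))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_round_trip_property(self, seed):
        coll = random_collection(seed=seed, n_docs=1, max_annotations=12)
        assert coll.content_equal(read_bioc(write_bioc(coll)))
        assert coll.content_equal(merge_a1(write_a1(coll)),
                                  include_normalization=False)

    def test_emitted_offsets_revalidate(self):
        coll = random_collection(seed=99)
        for produced in (merge_a1(write_a1(coll)), read_bioc(write_bioc(coll))):
            assert produced.validate() == []
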