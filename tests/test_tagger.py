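"""Dictionary tagging, variant rules, age patterns and normalization."""

import re

import pytest

from litcur import (MatchingPolicy, TextDocument, VariantIndexRecord,
                    annotate_document, bundled_clinical_lexicon,
                    compile_lexicon, normalize_variant, tag_ages,
                    tag_dictionary, tag_variants)
from litcur.tagger import LexiconEntry, LexiconError, load_variant_index

TABLE_CUIS = {
    "Autosomal dominant": "C0265385",
    "Autosomal recessive": "C0441748",
    "Homozygous": "C0019904",
    "Heterozygous": "C0019425",
    "Hemizygous": "C1881036",
    "Complete penetrance": "C1840470",
    "Reduced penetrance": "C1867989",
    "Variable penetrance and expressivity": "C3276568",
    "Incomplete penetrance of some features": "C2750454",
    "Incomplete, age-associated penetrance": "C3280136",
    "Age of patient (years)": "C0001779",
    "Age of onset (years)": "C0206132",
}


class TestLexiconCompile:
    def test_bundled_lexicon_terms_and_cuis(self, clinical_lexicon):
        entries = bundled_clinical_lexicon()
        assert {e.term: e.concept_id for e in entries} == TABLE_CUIS
        assert len({e.concept_type for e in entries}) == 5
        for term, cui in TABLE_CUIS.items():
            info = clinical_lexicon.lookup(term)
            assert info is not None and info[2] == cui

    def test_empty_lexicon_tags_nothing(self):
        lex = compile_lexicon([])
        doc = TextDocument("d", "heterozygous carriers were observed")
        assert tag_dictionary(doc, lex) == []

    def test_cross_type_collision_is_compile_error(self):
        entries = [
            LexiconEntry("homozygous", [], "Zygosity", "UMLS", "C0019904"),
            LexiconEntry("homozygous", [], "Penetrance", "UMLS", "C1840470"),
        ]
        with pytest.raises(LexiconError, match="homozygous"):
            compile_lexicon(entries)

    def test_compile_is_idempotent(self):
        entries = bundled_clinical_lexicon()
        a = compile_lexicon(entries)
        b = compile_lexicon(entries)
        assert a.surface_map == b.surface_map


class TestDictionaryTagging:
    def test_zygosity_sentence(self, clinical_lexicon):
        doc = TextDocument("d", "The proband was heterozygous for the variant.")
        (ann,) = tag_dictionary(doc, clinical_lexicon)
        assert ann.surface == "heterozygous"
        assert ann.normalization == ("UMLS", "C0019425")
        assert ann.provenance == "automatic"

    def test_inheritance_span_excludes_trailing_word(self, clinical_lexicon):
        doc = TextDocument("d", "with autosomal recessive inheritance in sibs")
        (ann,) = tag_dictionary(doc, clinical_lexicon)
        assert ann.surface == "autosomal recessive"
        assert ann.normalization == ("UMLS", "C0441748")

    def test_longest_match_wins_over_nested_term(self):
        lex = compile_lexicon([
            LexiconEntry("penetrance", [], "Penetrance", "UMLS", "C1840470"),
            LexiconEntry("reduced penetrance", [], "Penetrance", "UMLS",
                         "C1867989")])
        doc = TextDocument("d", "the family shows reduced penetrance overall")
        (ann,) = tag_dictionary(doc, lex)
        assert ann.surface == "reduced penetrance"
        assert ann.normalization[1] == "C1867989"

    def test_token_boundaries_prevent_substring_hits(self):
        lex = compile_lexicon([
            LexiconEntry("zygosity", [], "Zygosity", "UMLS", "C0019904")])
        doc = TextDocument("d", "heterozygosityX and zygosity differ")
        (ann,) = tag_dictionary(doc, lex)
        assert ann.fragments == ((20, 28),)

    def test_short_terms_match_case_sensitively(self):
        lex = compile_lexicon([LexiconEntry("ATM", [], "Gene", "HGNC", "795")],
                              MatchingPolicy(case_sensitive_max_length=4))
        hits = tag_dictionary(TextDocument("d", "the atm and ATM gene"), lex)
        assert [a.start for a in hits] == [12]

    def test_equivalence_with_brute_force_leftmost_longest(self, clinical_lexicon):
        """Scanning matcher equals enumerate-all-then-greedy-resolve oracle."""
        surfaces = list(clinical_lexicon.surface_map)
        import numpy as np
        rng = np.random.default_rng(42)
        fillers = ["alpha", "beta", "gamma", "delta", "x9"]
        for _ in range(50):
            tokens = []
            for _ in range(rng.integers(3, 25)):
                if rng.random() < 0.4:
                    tokens.append(str(surfaces[rng.integers(0, len(surfaces))]))
                else:
                    tokens.append(fillers[rng.integers(0, len(fillers))])
            text = " ".join(tokens)
            doc = TextDocument("d", text)
            got = [(a.start, a.end) for a in tag_dictionary(doc, clinical_lexicon)]
            # oracle: all boundary-respecting occurrences of every surface,
            # then leftmost-longest greedy selection
            candidates = []
            folded = text.casefold()
            for surf in surfaces:
                for m in re.finditer(re.escape(surf), folded):
                    s, e = m.span()
                    ok_before = s == 0 or not text[s - 1].isalnum()
                    ok_after = e == len(text) or not text[e].isalnum()
                    if ok_before and ok_after:
                        candidates.append((s, e))
            expected, last_end = [], 0
            for s, e in sorted(candidates, key=lambda c: (c[0], -c[1])):
                if s >= last_end:
                    expected.append((s, e))
                    last_end = e
            assert got == expected

    def test_idempotent_and_sorted(self, clinical_lexicon):
        doc = TextDocument("d", "homozygous then heterozygous then hemizygous")
        a = tag_dictionary(doc, clinical_lexicon)
        b = tag_dictionary(doc, clinical_lexicon)
        assert [x.content_key() for x in a] == [x.content_key() for x in b]
        assert [x.start for x in a] == sorted(x.start for x in a)
        for ann in a:
            assert ann.surface == doc.text[ann.start:ann.end]


class TestVariantRules:
    @pytest.mark.parametrize("mention,expected_type", [
        ("c.76A>T", "SNV"),
        ("g.31224G>A", "SNV"),
        ("c.88+1G>T", "SNV"),
        ("p.Gly12Asp", "SNV"),
        ("p.R117H", "SNV"),
        ("c.35delG", "InDel"),
        ("p.Phe508del", "InDel"),
        ("c.1521_1523delCTT", "InDel"),
        ("c.3067dupA", "InDel"),
        ("inv(16)", "Rearrangement"),
    ])
    def test_classification(self, mention, expected_type):
        doc = TextDocument("d", f"carrying {mention} in one allele")
        (ann,) = tag_variants(doc)
        assert ann.surface == mention
        assert ann.concept_type == expected_type

    def test_rs_number_carries_normalization_candidate(self):
        (ann,) = tag_variants(TextDocument("d", "the rs113993960 allele"))
        assert ann.concept_type == "SNV"
        assert ann.normalization == ("dbSNP", "rs113993960")

    def test_translocation_phrase_is_single_mention(self):
        (ann,) = tag_variants(TextDocument("d", "a t(9;22) translocation case"))
        assert ann.concept_type == "Rearrangement"
        assert ann.surface == "t(9;22) translocation"

    def test_no_hits_inside_words(self):
        assert tag_variants(TextDocument("d", "virs123 and Mdelta")) == []

    def test_merged_annotation_precedence(self, clinical_lexicon):
        doc = TextDocument(
            "d", "heterozygous for c.76A>T with reduced penetrance")
        anns = annotate_document(doc, lexicon=clinical_lexicon)
        assert [a.concept_type for a in anns] == ["Zygosity", "SNV", "Penetrance"]
        assert [a.ann_id for a in anns] == ["T1", "T2", "T3"]


class TestAges:
    def test_age_of_patient_and_onset(self):
        doc = TextDocument("d", "a patient aged 34 years with onset at age 5")
        anns = tag_ages(doc)
        assert [(a.concept_type, a.normalization[1]) for a in anns] == [
            ("Age of patient", "C0001779"), ("Age of onset", "C0206132")]


class TestNormalizeVariant:
    INDEX = [
        VariantIndexRecord("rs001", ["c.76A>T"], ["GENE1"]),
        VariantIndexRecord("rs002", ["c.76A>T", "c.100G>C"], ["GENE2"]),
        VariantIndexRecord("rs113993960", ["c.1521_1523delCTT"], ["CFTR"]),
    ]

    def test_unique_lookup(self):
        index = [VariantIndexRecord("rs001", ["c.76A>T"], ["GENE1"])]
        assert normalize_variant("c.76A>T", None, index) == "rs001"
        assert normalize_variant(" c.76a>t ", None, index) == "rs001"

    def test_gene_context_disambiguates(self):
        assert normalize_variant("c.76A>T", "GENE2", self.INDEX) == "rs002"
        assert normalize_variant("c.76A>T", None, self.INDEX) is None

    def test_miss_is_none_not_error(self):
        assert normalize_variant("c.999G>C", None, self.INDEX) is None

    def test_rs_mention_resolves_to_itself_when_indexed(self):
        assert normalize_variant("rs113993960", None, self.INDEX) == "rs113993960"
        assert normalize_variant("rs999", None, self.INDEX) is None

    def test_index_file_round_trip(self):
        from litcur.tagger import dump_variant_index
        text = dump_variant_index(self.INDEX)
        again = load_variant_index(text)
        assert [r.variant_id for r in again] == ["rs001", "rs002", "rs113993960"]
        with pytest.raises(LexiconError):
            load_variant_index(text + "rs001\tc.5A>T\t\n")
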