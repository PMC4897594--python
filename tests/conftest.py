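import pytest

from litcur import (AnnotatedCollection, AnnotationSetView, ConceptAnnotation,
                    TextDocument, bundled_clinical_lexicon, compile_lexicon)


@pytest.fixture(scope="session")
def clinical_lexicon():
    return compile_lexicon(bundled_clinical_lexicon())


@pytest.fixture
def make_ann():
    """Build a concept annotation on a synthetic all-'A' document text."""
    def _make(start, end, ctype, doc_id="doc1", ann_id=None, norm=None):
        return ConceptAnnotation(
            ann_id=ann_id or f"T{start}",
            doc_id=doc_id, concept_type=ctype, fragments=((start, end),),
            surface="A" * (end - start), normalization=norm)
    return _make


@pytest.fixture
def make_view(make_ann):
    def _make(curator_id, spans, doc_id="doc1"):
        anns = [make_ann(s, e, t, doc_id=doc_id, ann_id=f"T{i}")
                for i, (s, e, t) in enumerate(spans, 1)]
        return AnnotationSetView(curator_id=curator_id,
                                 annotations={doc_id: anns})
    return _make
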