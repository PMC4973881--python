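"""The 22-feature pairwise representation: text rules, AP, missing values."""

import numpy as np
import pandas as pd
import pytest

from seqdedup.alignment import AlignmentOutcome, Hsp, nucleotide_params
from seqdedup.features import (
    FEATURE_NAMES,
    NUMERIC_FEATURES,
    PairFeatures,
    alignment_features,
    compute_ap,
    compute_pair_features,
    description_similarity,
    jaccard,
    length_ratio,
    literature_similarity,
    read_feature_table,
    submitter_similarity,
    tokenize_description,
    write_feature_table,
)
from seqdedup.records import LiteratureRef, RecordPair, SequenceRecord


def _record(acc="A1", description="", references=(), submitters=None, sequence="ACGT" * 50):
    return SequenceRecord(
        accession=acc, organism="o", description=description,
        sequence=sequence, references=tuple(references), submitters=submitters,
    )


# --- text features ---------------------------------------------------------

def test_tokenize_lemmatizes_and_lowers():
    assert tokenize_description("Encoding protein X") == {"encode", "protein", "x"}


def test_tokenize_empty_and_duplicate_collapse():
    assert tokenize_description("") == set()
    assert tokenize_description("zinc zinc finger") == {"zinc", "finger"}


def test_tokenize_drops_stopwords():
    assert tokenize_description("the gene of a cell") == {"gene", "cell"}


@pytest.mark.parametrize(
    "a, b, expected",
    [({"a", "b"}, {"b", "c"}, 1 / 3), ({"x"}, {"x"}, 1.0), (set(), set(), 0.0)],
)
def test_jaccard(a, b, expected):
    assert jaccard(a, b) == pytest.approx(expected)


def test_description_similarity_is_order_insensitive():
    r1 = _record("A1", description="zinc finger protein mRNA")
    r2 = _record("A2", description="mRNA protein finger zinc")
    assert description_similarity(r1, r2) == 1.0
    r3 = _record("A3", description="unrelated words entirely")
    assert description_similarity(r1, r3) == 0.0


def _lit(pmid=None, journal=None, title=None, authors=()):
    return LiteratureRef(pubmed_id=pmid, journal=journal, title=title,
                         authors=frozenset(authors))


def test_literature_shared_pmid_is_boolean_match():
    r1 = _record("A1", references=[_lit(pmid="12345", journal="J1", title="t one")])
    r2 = _record("A2", references=[_lit(pmid="12345", journal="J2", title="t two")])
    assert literature_similarity(r1, r2) == ("Yes", 1.0)


def test_literature_pmid_mismatch_scores_zero():
    r1 = _record("A1", references=[_lit(pmid="1")])
    r2 = _record("A2", references=[_lit(pmid="2")])
    assert literature_similarity(r1, r2) == ("Yes", 0.0)


def test_literature_falls_back_to_title_tokens():
    r1 = _record("A1", references=[_lit(journal="J", title="Encoding zinc fingers")])
    r2 = _record("A2", references=[_lit(journal="K", title="zinc finger encoding")])
    has, value = literature_similarity(r1, r2)
    assert has == "Yes"
    assert value == 1.0


def test_literature_falls_back_to_authors():
    r1 = _record("A1", references=[_lit(authors={"smith,j.", "lee,k."})])
    r2 = _record("A2", references=[_lit(authors={"smith,j."})])
    assert literature_similarity(r1, r2) == ("Yes", 0.5)


def test_literature_absent_on_either_side_means_no():
    r1 = _record("A1", references=[_lit(pmid="1")])
    r2 = _record("A2")
    assert literature_similarity(r1, r2) == ("No", None)


def test_submitter_rules():
    a = _record("A1", submitters=frozenset({"smith,j."}))
    b = _record("A2", submitters=frozenset({"smith,j.", "lee,k."}))
    c = _record("A3", submitters=frozenset({"chen,x."}))
    d = _record("A4", submitters=None)
    assert submitter_similarity(a, b) == "SAME"
    assert submitter_similarity(a, c) == "DIFFERENT"
    assert submitter_similarity(a, d) == "NA"


def test_length_ratio():
    assert length_ratio(100, 100) == 1.0
    assert length_ratio(72, 100) == pytest.approx(0.72)
    assert length_ratio(100, 72) == length_ratio(72, 100)
    with pytest.raises(ValueError):
        length_ratio(0, 10)


# --- alignment-derived features -------------------------------------------

def _outcome(*nident_lengths):
    hsps = tuple(
        Hsp(identity_fraction=ni / al, num_identical=ni, align_length=al,
            evalue=1e-10 * (k + 1), score=100 - k)
        for k, (ni, al) in enumerate(nident_lengths)
    )
    return AlignmentOutcome(has_hits=bool(hsps), hsps=hsps)


def test_compute_ap_direct_substitution():
    assert compute_ap(_outcome((50, 50)), 100, 80) == pytest.approx(0.5)


def test_compute_ap_union_mode_sums_hsps():
    outcome = _outcome((50, 50), (30, 30))
    assert compute_ap(outcome, 100, 100) == pytest.approx(0.5)
    assert compute_ap(outcome, 100, 100, ap_mode="union") == pytest.approx(0.8)


def test_compute_ap_requires_hits():
    with pytest.raises(ValueError):
        compute_ap(AlignmentOutcome(has_hits=False), 100, 100)


def test_alignment_features_identical_sequences(rng):
    seq = "".join(rng.choice(list("ACGT"), 500))
    has, identity, ap, evalue, over = alignment_features(seq, seq, nucleotide_params())
    assert has == "Yes"
    assert identity == 1.0
    assert ap == pytest.approx(1.0)
    assert over == "No"


def test_alignment_features_substring_ap(rng):
    parent = "".join(rng.choice(list("ACGT"), 300))
    has, identity, ap, _, _ = alignment_features(parent, parent[:150], nucleotide_params())
    assert identity == 1.0
    assert ap == pytest.approx(0.5)


def test_alignment_features_no_hits_pattern(rng):
    # sequences with no positive-scoring local match produce no hits
    has, identity, ap, evalue, over = alignment_features(
        "AAAAAAAAAA", "CCCCCCCCCC", nucleotide_params()
    )
    assert (has, identity, ap, evalue, over) == ("No", None, None, None, "Yes")


# --- whole-pair feature vectors -------------------------------------------

def test_feature_vector_has_exactly_22_features(small_features):
    assert len(FEATURE_NAMES) == 22
    assert [c for c in small_features.columns if c in FEATURE_NAMES] == list(FEATURE_NAMES)


def test_es_pair_has_high_identity_and_ap(small_corpus, small_features):
    es_mask = (small_features["subtype"] == "ES").to_numpy()
    assert (small_features.loc[es_mask, "Identity"] >= 0.9).all()
    assert (small_features.loc[es_mask, "AP"] >= 0.9).all()


def test_pair_without_cds_has_missing_cds_block():
    r1 = _record("A1", sequence="ACGT" * 100)
    r2 = _record("A2", sequence="ACGT" * 100)
    feats = compute_pair_features(RecordPair(r1, r2))
    assert feats.has_cds == "No"
    assert feats.cds_hits == "No" and feats.trs_hits == "No"
    assert feats.cds_identity is None and feats.trs_identity is None
    assert feats.cds_threshold == "Yes" and feats.trs_threshold == "Yes"


def test_features_symmetric_under_pair_swap(small_corpus):
    for pair in small_corpus.pairs[::9]:
        fwd = compute_pair_features(pair)
        rev = compute_pair_features(RecordPair(pair.record_b, pair.record_a, pair.label))
        assert fwd.to_dict() == rev.to_dict()


def test_ranges_and_missing_coupling_hold_on_corpus(small_features):
    df = small_features
    for unit_col in ("Description", "Literature", "Length", "Identity", "AP",
                     "CDS_Identity", "CDS_AP", "TRS_Identity", "TRS_AP"):
        values = df[unit_col].dropna()
        assert ((values >= 0) & (values <= 1)).all(), unit_col
    for expect_col in ("Expect_Value", "CDS_Expect", "TRS_Expect"):
        assert (df[expect_col].dropna() >= 0).all()
    for flag, deps in (
        ("Has_HITS", ("Identity", "AP", "Expect_Value")),
        ("CDS_HITS", ("CDS_Identity", "CDS_AP", "CDS_Expect")),
        ("TRS_HITS", ("TRS_Identity", "TRS_AP", "TRS_Expect")),
    ):
        no_hits = df[flag] == "No"
        for dep in deps:
            assert df.loc[no_hits, dep].isna().all()


def test_missing_value_coupling_enforced_at_construction():
    kwargs = dict(
        description=0.5, has_literature="No", literature=None, submitter="NA",
        length=1.0, has_hits="No", identity=0.9, ap=None, expect_value=None,
        over_threshold="Yes", has_cds="No", cds_hits="No", cds_identity=None,
        cds_ap=None, cds_expect=None, cds_threshold="Yes", has_trs="No",
        trs_hits="No", trs_identity=None, trs_ap=None, trs_expect=None,
        trs_threshold="Yes",
    )
    with pytest.raises(ValueError, match="identity must be missing"):
        PairFeatures(**kwargs)


def test_feature_table_tsv_roundtrip(small_features, tmp_path):
    path = tmp_path / "features.tsv"
    write_feature_table(small_features, path)
    back = read_feature_table(path)
    assert list(back.columns) == list(small_features.columns)
    # Submitter's literal "NA" value survives; missing numerics decode as NaN
    assert set(back["Submitter"]) <= {"SAME", "DIFFERENT", "NA"}
    for col in NUMERIC_FEATURES:
        np.testing.assert_allclose(
            back[col].to_numpy(dtype=float),
            small_features[col].to_numpy(dtype=float),
            rtol=1e-9, equal_nan=True,
        )
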