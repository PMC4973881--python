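"""The 22-feature pairwise representation of a record pair.

A candidate duplicate pair is summarised by metadata similarity
(description tokens, literature references, submitters), a length ratio,
and three blocks of local-alignment statistics: the whole sequences, the
first coding region (CDS) of each record, and the protein translations
(TRS) of those regions.  Each alignment block contributes a hit flag,
local identity, aligned proportion (AP), E-value, and a significance flag.

Missing-value semantics are part of the schema: when an alignment has no
hits the dependent numeric features are missing (not zero) and the
``*_Threshold`` flag is "Yes", treating "no significant similarity" as the
extreme of a non-significant alignment.

AP estimates global coverage without a global alignment::

    AP = len(I) / max(len(D), len(R))

where len(I) is the number of locally aligned identical bases (best HSP by
default) and len(D), len(R) are the two sequence lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

from seqdedup._text import tokenize
from seqdedup.alignment import (
    AlignmentOutcome,
    AlignParams,
    align_pair,
    nucleotide_params,
    protein_params,
)
from seqdedup.records import RecordPair, SequenceRecord, first_cds

__all__ = [
    "PairFeatures",
    "FEATURE_NAMES",
    "NUMERIC_FEATURES",
    "CATEGORICAL_FEATURES",
    "EVALUE_SIGNIFICANCE_THRESHOLD",
    "tokenize_description",
    "jaccard",
    "description_similarity",
    "literature_similarity",
    "submitter_similarity",
    "length_ratio",
    "compute_ap",
    "alignment_features",
    "compute_pair_features",
    "compute_feature_table",
    "write_feature_table",
    "read_feature_table",
]

#: E-value significance cutoff for the Over_Threshold family of features.
EVALUE_SIGNIFICANCE_THRESHOLD = 0.001

#: Canonical feature order (metadata, whole sequence, CDS, translations).
FEATURE_NAMES: tuple[str, ...] = (
    "Description",
    "Has_Literature",
    "Literature",
    "Submitter",
    "Length",
    "Has_HITS",
    "Identity",
    "AP",
    "Expect_Value",
    "Over_Threshold",
    "Has_CDS",
    "CDS_HITS",
    "CDS_Identity",
    "CDS_AP",
    "CDS_Expect",
    "CDS_Threshold",
    "Has_TRS",
    "TRS_HITS",
    "TRS_Identity",
    "TRS_AP",
    "TRS_Expect",
    "TRS_Threshold",
)

NUMERIC_FEATURES: tuple[str, ...] = (
    "Description",
    "Literature",
    "Length",
    "Identity",
    "AP",
    "Expect_Value",
    "CDS_Identity",
    "CDS_AP",
    "CDS_Expect",
    "TRS_Identity",
    "TRS_AP",
    "TRS_Expect",
)

CATEGORICAL_FEATURES: tuple[str, ...] = tuple(
    n for n in FEATURE_NAMES if n not in NUMERIC_FEATURES
)

_FIELD_TO_NAME = {
    "description": "Description",
    "has_literature": "Has_Literature",
    "literature": "Literature",
    "submitter": "Submitter",
    "length": "Length",
    "has_hits": "Has_HITS",
    "identity": "Identity",
    "ap": "AP",
    "expect_value": "Expect_Value",
    "over_threshold": "Over_Threshold",
    "has_cds": "Has_CDS",
    "cds_hits": "CDS_HITS",
    "cds_identity": "CDS_Identity",
    "cds_ap": "CDS_AP",
    "cds_expect": "CDS_Expect",
    "cds_threshold": "CDS_Threshold",
    "has_trs": "Has_TRS",
    "trs_hits": "TRS_HITS",
    "trs_identity": "TRS_Identity",
    "trs_ap": "TRS_AP",
    "trs_expect": "TRS_Expect",
    "trs_threshold": "TRS_Threshold",
}
_NAME_TO_FIELD = {v: k for k, v in _FIELD_TO_NAME.items()}


@dataclass(frozen=True)
class PairFeatures:
    """The 22 features for one record pair, with missing-value semantics."""

    description: float
    has_literature: str
    literature: Optional[float]
    submitter: str
    length: float
    has_hits: str
    identity: Optional[float]
    ap: Optional[float]
    expect_value: Optional[float]
    over_threshold: str
    has_cds: str
    cds_hits: str
    cds_identity: Optional[float]
    cds_ap: Optional[float]
    cds_expect: Optional[float]
    cds_threshold: str
    has_trs: str
    trs_hits: str
    trs_identity: Optional[float]
    trs_ap: Optional[float]
    trs_expect: Optional[float]
    trs_threshold: str

    def __post_init__(self) -> None:
        for flag, deps in (
            ("has_hits", ("identity", "ap", "expect_value")),
            ("cds_hits", ("cds_identity", "cds_ap", "cds_expect")),
            ("trs_hits", ("trs_identity", "trs_ap", "trs_expect")),
        ):
            if getattr(self, flag) == "No":
                for dep in deps:
                    if getattr(self, dep) is not None:
                        raise ValueError(f"{dep} must be missing when {flag} == No")

    def to_dict(self) -> dict[str, object]:
        """Feature values keyed by canonical feature names, in order."""
        return {name: getattr(self, _NAME_TO_FIELD[name]) for name in FEATURE_NAMES}


def tokenize_description(text: str) -> set[str]:
    """Token set of a description: lowercase, stopword-free, lemmatized."""
    return tokenize(text)


def jaccard(set_a: Iterable, set_b: Iterable) -> float:
    """|A ∩ B| / |A ∪ B|; two empty sets score 0.0 (no shared evidence)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def description_similarity(r1: SequenceRecord, r2: SequenceRecord) -> float:
    """Jaccard similarity of description token sets (order-insensitive)."""
    return jaccard(tokenize_description(r1.description), tokenize_description(r2.description))


def literature_similarity(
    r1: SequenceRecord, r2: SequenceRecord
) -> tuple[str, Optional[float]]:
    """(Has_Literature, Literature) from the pooled citations of each record.

    Rule cascade when both records carry at least one citation:

    1. both sides have PubMed IDs -> Boolean match (1.0 if any shared ID);
    2. else both have a JOURNAL entry -> token Jaccard of titles;
    3. else -> Jaccard of the pooled author-name sets.
    """
    refs1, refs2 = r1.references, r2.references
    if not refs1 or not refs2:
        return "No", None
    pmids1 = {r.pubmed_id for r in refs1 if r.pubmed_id}
    pmids2 = {r.pubmed_id for r in refs2 if r.pubmed_id}
    if pmids1 and pmids2:
        return "Yes", 1.0 if pmids1 & pmids2 else 0.0
    journal1 = next((r for r in refs1 if r.journal), None)
    journal2 = next((r for r in refs2 if r.journal), None)
    if journal1 is not None and journal2 is not None:
        return "Yes", jaccard(tokenize(journal1.title or ""), tokenize(journal2.title or ""))
    authors1 = set().union(*(r.authors for r in refs1))
    authors2 = set().union(*(r.authors for r in refs2))
    return "Yes", jaccard(authors1, authors2)


def submitter_similarity(r1: SequenceRecord, r2: SequenceRecord) -> str:
    """SAME if the submitter sets intersect, DIFFERENT if not, NA if absent.

    INSDC policy lets any one original submitter update a record, so a
    single shared name is enough for SAME.
    """
    if r1.submitters is None or r2.submitters is None:
        return "NA"
    return "SAME" if r1.submitters & r2.submitters else "DIFFERENT"


def length_ratio(len_a: int, len_b: int) -> float:
    """min/max of two sequence lengths; symmetric, in (0, 1]."""
    if len_a <= 0 or len_b <= 0:
        raise ValueError("sequence lengths must be positive")
    return min(len_a, len_b) / max(len_a, len_b)


ApMode = Literal["best_hsp", "union"]


def compute_ap(
    outcome: AlignmentOutcome, len_d: int, len_r: int, ap_mode: ApMode = "best_hsp"
) -> float:
    """Aligned proportion: identical aligned bases over the longer length.

    ``best_hsp`` counts identical bases of the best HSP only (default);
    ``union`` sums over the reported non-overlapping HSPs.
    """
    if not outcome.has_hits:
        raise ValueError("AP undefined without hits; feature must be missing")
    if ap_mode == "best_hsp":
        len_i = outcome.best.num_identical
    elif ap_mode == "union":
        len_i = sum(h.num_identical for h in outcome.hsps)
    else:
        raise ValueError(f"unknown ap_mode {ap_mode!r}")
    return min(len_i / max(len_d, len_r), 1.0)


def alignment_features(
    seq_a: str,
    seq_b: str,
    params: Optional[AlignParams] = None,
    backend: str = "internal",
    ap_mode: ApMode = "best_hsp",
) -> tuple[str, Optional[float], Optional[float], Optional[float], str]:
    """(Has_HITS, Identity, AP, Expect_Value, Over_Threshold) for one pair.

    Over_Threshold is "Yes" when there is no hit at all or when the best
    E-value strictly exceeds 0.001.
    """
    outcome = align_pair(seq_a, seq_b, params, backend=backend)
    if not outcome.has_hits:
        return "No", None, None, None, "Yes"
    best = outcome.best
    ap = compute_ap(outcome, len(seq_a), len(seq_b), ap_mode=ap_mode)
    over = "Yes" if best.evalue > EVALUE_SIGNIFICANCE_THRESHOLD else "No"
    return "Yes", best.identity_fraction, ap, best.evalue, over


def compute_pair_features(
    pair: RecordPair,
    backend: str = "internal",
    nuc_params: Optional[AlignParams] = None,
    prot_params: Optional[AlignParams] = None,
    ap_mode: ApMode = "best_hsp",
) -> PairFeatures:
    """Compute all 22 features for a record pair.

    Whole sequences and first-CDS nucleotide sequences are aligned in
    nucleotide mode (word size 4, dusting off); first-CDS translations in
    protein mode (word size 2).  Degenerate inputs (no CDS, no translation,
    no hits) produce missing/"No" values rather than errors.
    """
    r1, r2 = pair.record_a, pair.record_b
    nuc_params = nuc_params or nucleotide_params()
    prot_params = prot_params or protein_params()

    has_lit, literature = literature_similarity(r1, r2)
    seq_feats = alignment_features(
        r1.sequence, r2.sequence, nuc_params, backend=backend, ap_mode=ap_mode
    )

    cds1, cds2 = first_cds(r1), first_cds(r2)
    if cds1 is not None and cds2 is not None:
        has_cds = "Yes"
        cds_feats = alignment_features(
            cds1[0], cds2[0], nuc_params, backend=backend, ap_mode=ap_mode
        )
        trs1, trs2 = cds1[1], cds2[1]
        if trs1 and trs2:
            has_trs = "Yes"
            trs_feats = alignment_features(
                trs1, trs2, prot_params, backend=backend, ap_mode=ap_mode
            )
        else:
            has_trs = "No"
            trs_feats = ("No", None, None, None, "Yes")
    else:
        has_cds = "No"
        has_trs = "No"
        cds_feats = ("No", None, None, None, "Yes")
        trs_feats = ("No", None, None, None, "Yes")

    return PairFeatures(
        description=description_similarity(r1, r2),
        has_literature=has_lit,
        literature=literature,
        submitter=submitter_similarity(r1, r2),
        length=length_ratio(len(r1), len(r2)),
        has_hits=seq_feats[0],
        identity=seq_feats[1],
        ap=seq_feats[2],
        expect_value=seq_feats[3],
        over_threshold=seq_feats[4],
        has_cds=has_cds,
        cds_hits=cds_feats[0],
        cds_identity=cds_feats[1],
        cds_ap=cds_feats[2],
        cds_expect=cds_feats[3],
        cds_threshold=cds_feats[4],
        has_trs=has_trs,
        trs_hits=trs_feats[0],
        trs_identity=trs_feats[1],
        trs_ap=trs_feats[2],
        trs_expect=trs_feats[3],
        trs_threshold=trs_feats[4],
    )


def compute_feature_table(
    pairs: Sequence[RecordPair],
    backend: str = "internal",
    nuc_params: Optional[AlignParams] = None,
    prot_params: Optional[AlignParams] = None,
    ap_mode: ApMode = "best_hsp",
) -> pd.DataFrame:
    """Feature matrix: one row per pair, 22 named columns, plus accessions
    and (when pairs are labelled) ``label`` / ``subtype`` columns."""
    rows = []
    for pair in pairs:
        feats = compute_pair_features(
            pair, backend=backend, nuc_params=nuc_params,
            prot_params=prot_params, ap_mode=ap_mode,
        )
        row: dict[str, object] = {
            "accession_a": pair.record_a.accession,
            "accession_b": pair.record_b.accession,
        }
        row.update(feats.to_dict())
        if pair.label is not None:
            row["label"] = pair.label.binary
            row["subtype"] = pair.label.subtype or ""
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in NUMERIC_FEATURES:
        df[col] = pd.to_numeric(df[col])
    return df


def write_feature_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a feature matrix as TSV; missing numerics encoded as NA."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_feature_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a feature-matrix TSV written by :func:`write_feature_table`.

    "NA" is a legitimate *value* of the Submitter column, so missingness
    is decoded only for numeric columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in NUMERIC_FEATURES:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col].replace("NA", np.nan))
    return df
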