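"""Pair labels, duplicate-subtype assignment, and the Seq90 baseline.

Duplicates (DU) are subdivided by alignment evidence:

* **ES** (near-exact sequence) — Identity and AP both at least 0.9;
* **EF** (near-exact fragment) — a significant hit, but below ES criteria;
* **NS** (non-significant alignment) — no hit at all, or E-value over
  0.001: the alignment carries no trustworthy identity evidence.

NS is evaluated first because membership in it invalidates the identity
values that the ES/EF rules rely on; the precedence is NS -> ES -> EF and
the rule is total over valid feature vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from seqdedup.features import PairFeatures

__all__ = ["PairLabel", "SUBTYPES", "assign_subtype", "seq90_classify"]

SUBTYPES = ("ES", "EF", "NS")

#: Identity / AP threshold for the ES subtype (inclusive).
ES_THRESHOLD = 0.9
#: Seq90 baseline threshold on Identity and Length (inclusive).
SEQ90_THRESHOLD = 0.9


@dataclass(frozen=True)
class PairLabel:
    """Binary label (DU/DI) plus the duplicate subtype for DU pairs."""

    binary: str
    subtype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.binary not in ("DU", "DI"):
            raise ValueError(f"binary label must be DU or DI, got {self.binary!r}")
        if self.binary == "DU":
            if self.subtype is not None and self.subtype not in SUBTYPES:
                raise ValueError(f"unknown subtype {self.subtype!r}")
        elif self.subtype is not None:
            raise ValueError("distinct pairs carry no subtype")


def assign_subtype(f: PairFeatures) -> str:
    """Assign ES/EF/NS to a known duplicate pair from its features.

    Precedence NS -> ES -> EF.  The significance boundary is strict
    (E-value exactly 0.001 is still significant); the ES identity/AP
    boundaries are inclusive ("not less than 0.9").
    """
    if f.over_threshold == "Yes":  # covers has_hits == "No"
        return "NS"
    if f.identity is not None and f.ap is not None and (
        f.identity >= ES_THRESHOLD and f.ap >= ES_THRESHOLD
    ):
        return "ES"
    return "EF"


def seq90_classify(f: PairFeatures) -> str:
    """Sequence-similarity baseline: DU iff Identity and Length >= 0.9.

    A pair without an alignment hit has no identity value and cannot be
    claimed as a duplicate, so it is classified DI.
    """
    if f.identity is None:
        return "DI"
    if f.identity >= SEQ90_THRESHOLD and f.length >= SEQ90_THRESHOLD:
        return "DU"
    return "DI"
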