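"""Pairwise local alignment statistics behind a single backend contract.

Duplicate-detection features need four things from an alignment of two
sequences: whether any significant local hit exists, the local identity of
the best high-scoring segment pair (HSP), the number of identical aligned
bases, and the E-value.  Two backends provide them:

* ``internal`` — affine-gap Smith–Waterman (biotite's optimal-alignment DP)
  with BLAST-compatible scoring (nucleotide: match +2 / mismatch -3, gap
  open 5 / extend 2; protein: BLOSUM62, open 11 / extend 1).  E-values come
  from the Karlin–Altschul formula E = K·m'·n'·exp(-lambda·S) with the
  published gapped parameters for those scoring schemes and the standard
  iterative length adjustment of the effective search space.  Suboptimal
  HSPs are recovered by masking the best HSP's span and re-aligning.
* ``external`` — the NCBI BLAST+ command line (blastn/blastp run in
  pairwise query-vs-subject mode) with low-complexity filtering disabled
  and the minimum word size (4 for nucleotide, 2 for protein), parsed from
  tabular output.

The two agree on hit calls and identical-base counts for related sequences;
exact E-values differ because BLAST applies sum statistics the internal
model does not attempt.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign

__all__ = [
    "Hsp",
    "AlignmentOutcome",
    "AlignParams",
    "nucleotide_params",
    "protein_params",
    "align_pair",
    "internal_local_align",
    "parse_blast_tabular",
    "BlastTabularError",
    "BackendUnavailableError",
    "AlignmentSizeError",
]

Mode = Literal["nucleotide", "protein"]

# Gapped Karlin-Altschul parameters (lambda, K, H) for the two scoring
# schemes, as tabulated for BLAST: reward 2 / penalty -3 / gap 5,2 and
# BLOSUM62 / gap 11,1.
_KA_PARAMS = {
    "nucleotide": (0.625, 0.41, 0.78),
    "protein": (0.267, 0.041, 0.140),
}
_NUC_MATCH, _NUC_MISMATCH = 2, -3
_NUC_GAP_OPEN, _NUC_GAP_EXTEND = 5, 2
_PROT_GAP_OPEN, _PROT_GAP_EXTEND = 11, 1


class BackendUnavailableError(RuntimeError):
    """The external alignment executable cannot be found or fails to run."""


class AlignmentSizeError(ValueError):
    """Input exceeds the quadratic-DP length cap of the internal engine."""


class BlastTabularError(ValueError):
    """A tabular alignment report line could not be parsed."""


@dataclass(frozen=True)
class Hsp:
    """One high-scoring segment pair.

    ``identity_fraction`` uses the BLAST convention: identical positions
    divided by alignment length including gap columns.
    """

    identity_fraction: float
    num_identical: int
    align_length: int
    evalue: float
    score: float

    def __post_init__(self) -> None:
        if not 0 <= self.num_identical <= self.align_length:
            raise ValueError("num_identical must lie in [0, align_length]")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class AlignmentOutcome:
    """Hit flag plus HSPs ordered best-first (E-value asc, score desc)."""

    has_hits: bool
    hsps: tuple[Hsp, ...] = ()

    def __post_init__(self) -> None:
        if self.has_hits != bool(self.hsps):
            raise ValueError("has_hits must equal bool(hsps)")

    @property
    def best(self) -> Hsp:
        if not self.hsps:
            raise ValueError("no hits: best HSP undefined")
        return self.hsps[0]


@dataclass(frozen=True)
class AlignParams:
    """Alignment settings shared by both backends.

    ``evalue_report_cutoff`` mirrors the BLAST default report threshold of
    10; significance at 0.001 is a downstream feature, not applied here.
    ``max_hsps`` bounds the iterative-masking search for suboptimal HSPs in
    the internal engine (1 = best HSP only, which is all the feature set
    consumes).  ``max_internal_length`` guards the quadratic DP.
    """

    mode: Mode = "nucleotide"
    word_size: int = 4
    masking_enabled: bool = False
    evalue_report_cutoff: float = 10.0
    max_hsps: int = 1
    max_internal_length: int = 20_000


def nucleotide_params(**overrides) -> AlignParams:
    """Defaults for nucleotide mode: word size 4, dusting disabled."""
    return replace(AlignParams(mode="nucleotide", word_size=4), **overrides)


def protein_params(**overrides) -> AlignParams:
    """Defaults for protein mode: word size 2, SEG filtering disabled."""
    return replace(AlignParams(mode="protein", word_size=2), **overrides)


# --- internal engine -------------------------------------------------------

_NUC_ALPHABET = bseq.NucleotideSequence.alphabet_amb
_PROT_ALPHABET = bseq.ProteinSequence.alphabet


def _nucleotide_matrix() -> balign.SubstitutionMatrix:
    n = len(_NUC_ALPHABET)
    scores = np.full((n, n), _NUC_MISMATCH, dtype=np.int32)
    for base in "ACGT":
        i = _NUC_ALPHABET.encode(base)
        scores[i, i] = _NUC_MATCH
    return balign.SubstitutionMatrix(_NUC_ALPHABET, _NUC_ALPHABET, scores)


_NUC_MATRIX = _nucleotide_matrix()
_PROT_MATRIX = balign.SubstitutionMatrix.std_protein_matrix()  # BLOSUM62


def _length_adjustment(m: int, n: int, lam: float, K: float, H: float) -> int:
    """Iterative effective-length adjustment, as in BLAST's statistics.

    Shrinks both sequence lengths by the expected HSP length so short
    sequences are not credited with the full m*n search space.
    """
    ell = 0.0
    for _ in range(20):
        m_eff = max(m - ell, 1.0)
        n_eff = max(n - ell, 1.0)
        space = K * m_eff * n_eff
        if space <= 1.0:
            break
        ell_next = math.log(space) / H
        if abs(ell_next - ell) < 0.5:
            ell = ell_next
            break
        ell = ell_next
    ell = min(ell, m - 1, n - 1)
    return max(int(ell), 0)


def karlin_altschul_evalue(score: float, m: int, n: int, mode: Mode) -> float:
    """E = K * m' * n' * exp(-lambda * S) with effective lengths m', n'."""
    lam, K, H = _KA_PARAMS[mode]
    m, n = sorted((m, n))  # exact symmetry under argument swap
    ell = _length_adjustment(m, n, lam, K, H)
    m_eff = max(m - ell, 1)
    n_eff = max(n - ell, 1)
    return K * m_eff * n_eff * math.exp(-lam * score)


def _encode(sequence: str, mode: Mode):
    sequence = sequence.upper()
    try:
        if mode == "nucleotide":
            seq_obj = bseq.NucleotideSequence(sequence.replace("U", "T"))
        else:
            seq_obj = bseq.ProteinSequence(sequence.replace("*", "X"))
    except Exception as exc:
        raise ValueError(f"sequence does not match {mode} alphabet: {exc}") from exc
    return seq_obj


def _hsp_from_alignment(
    aln: balign.Alignment, m: int, n: int, mode: Mode
) -> tuple[Hsp, tuple[int, int], tuple[int, int]]:
    codes = balign.get_codes(aln)
    valid = (codes[0] != -1) & (codes[1] != -1)
    num_identical = int(((codes[0] == codes[1]) & valid).sum())
    align_length = codes.shape[1]
    evalue = karlin_altschul_evalue(aln.score, m, n, mode)
    hsp = Hsp(
        identity_fraction=num_identical / align_length if align_length else 0.0,
        num_identical=num_identical,
        align_length=align_length,
        evalue=evalue,
        score=float(aln.score),
    )
    trace = aln.trace
    span_a = (int(trace[:, 0][trace[:, 0] >= 0].min()), int(trace[:, 0].max()) + 1)
    span_b = (int(trace[:, 1][trace[:, 1] >= 0].min()), int(trace[:, 1].max()) + 1)
    return hsp, span_a, span_b


def internal_local_align(
    seq_a: str, seq_b: str, params: Optional[AlignParams] = None
) -> AlignmentOutcome:
    """Affine-gap Smith–Waterman local alignment with model-based E-values.

    Returns the best HSP and, when ``params.max_hsps`` allows, non-overlapping
    suboptimal HSPs found by masking previous HSP spans and re-aligning.
    """
    params = params or AlignParams()
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if max(len(seq_a), len(seq_b)) > params.max_internal_length:
        raise AlignmentSizeError(
            f"sequence length exceeds internal cap {params.max_internal_length}"
        )
    mode = params.mode
    if mode == "nucleotide":
        matrix = _NUC_MATRIX
        # biotite charges open for the first gap column; BLAST's open cost
        # excludes it, so open here = open + extend
        gap = (-(_NUC_GAP_OPEN + _NUC_GAP_EXTEND), -_NUC_GAP_EXTEND)
        mask_char = "N"
    else:
        matrix = _PROT_MATRIX
        gap = (-(_PROT_GAP_OPEN + _PROT_GAP_EXTEND), -_PROT_GAP_EXTEND)
        mask_char = "X"

    m, n = len(seq_a), len(seq_b)
    work_a, work_b = seq_a.upper(), seq_b.upper()
    hsps: list[Hsp] = []
    for _ in range(max(params.max_hsps, 1)):
        try:
            obj_a = _encode(work_a, mode)
            obj_b = _encode(work_b, mode)
        except ValueError:
            if hsps:
                break
            raise
        alns = balign.align_optimal(
            obj_a, obj_b, matrix, gap_penalty=gap, local=True, max_number=1
        )
        if not alns or alns[0].score <= 0 or alns[0].trace.shape[0] == 0:
            break
        hsp, span_a, span_b = _hsp_from_alignment(alns[0], m, n, mode)
        if hsp.evalue > params.evalue_report_cutoff:
            break
        hsps.append(hsp)
        # mask the consumed spans so the next round finds a disjoint HSP
        work_a = work_a[: span_a[0]] + mask_char * (span_a[1] - span_a[0]) + work_a[span_a[1]:]
        work_b = work_b[: span_b[0]] + mask_char * (span_b[1] - span_b[0]) + work_b[span_b[1]:]

    hsps.sort(key=lambda h: (h.evalue, -h.score))
    return AlignmentOutcome(has_hits=bool(hsps), hsps=tuple(hsps))


# --- external engine -------------------------------------------------------

_OUTFMT = "6 pident length nident evalue bitscore score"


def parse_blast_tabular(text: str) -> AlignmentOutcome:
    """Parse a BLAST tabular report (pident, length, nident, evalue, score).

    An empty report body means no hits.  Malformed lines raise
    :class:`BlastTabularError` with the offending line number.
    """
    hsps: list[Hsp] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            fields = line.split()
        try:
            pident, length, nident, evalue, _bitscore, score = fields[:6]
            hsps.append(
                Hsp(
                    identity_fraction=float(pident) / 100.0,
                    num_identical=int(nident),
                    align_length=int(length),
                    evalue=float(evalue),
                    score=float(score),
                )
            )
        except (ValueError, IndexError) as exc:
            raise BlastTabularError(f"line {lineno}: cannot parse {line!r}") from exc
    hsps.sort(key=lambda h: (h.evalue, -h.score))
    return AlignmentOutcome(has_hits=bool(hsps), hsps=tuple(hsps))


def _blast_executable(mode: Mode) -> str:
    name = "blastn" if mode == "nucleotide" else "blastp"
    path = shutil.which(name)
    if path is None:
        raise BackendUnavailableError(f"{name} not found on PATH")
    return path


def external_blast_align(
    seq_a: str, seq_b: str, params: Optional[AlignParams] = None
) -> AlignmentOutcome:
    """Run pairwise BLAST (query vs subject) and parse its tabular output.

    Low-complexity filtering is disabled (``-dust no`` / ``-seg no``) and
    the minimum word size is used, following the settings recommended for
    reliable pairwise record comparison.
    """
    params = params or AlignParams()
    exe = _blast_executable(params.mode)
    with tempfile.TemporaryDirectory() as tmp:
        qpath = Path(tmp) / "query.fa"
        spath = Path(tmp) / "subject.fa"
        qpath.write_text(f">query\n{seq_a}\n")
        spath.write_text(f">subject\n{seq_b}\n")
        cmd = [
            exe,
            "-query", str(qpath),
            "-subject", str(spath),
            "-word_size", str(params.word_size),
            "-evalue", str(params.evalue_report_cutoff),
            "-outfmt", _OUTFMT,
        ]
        if params.mode == "nucleotide":
            cmd += ["-task", "blastn", "-dust", "dust" if params.masking_enabled else "no"]
            if not params.masking_enabled:
                cmd += ["-soft_masking", "false"]
        else:
            cmd += ["-seg", "yes" if params.masking_enabled else "no"]
        try:
            proc = subprocess.run(
                cmd, capture_output=True, text=True, check=True, timeout=120
            )
        except FileNotFoundError as exc:  # pragma: no cover - guarded above
            raise BackendUnavailableError(str(exc)) from exc
        except subprocess.CalledProcessError as exc:
            raise BackendUnavailableError(
                f"{exe} exited {exc.returncode}: {exc.stderr.strip()}"
            ) from exc
    return parse_blast_tabular(proc.stdout)


def align_pair(
    seq_a: str,
    seq_b: str,
    params: Optional[AlignParams] = None,
    backend: Literal["internal", "external"] = "internal",
) -> AlignmentOutcome:
    """Align two sequences locally and return hit flag plus ordered HSPs."""
    params = params or AlignParams()
    if backend == "external":
        return external_blast_align(seq_a, seq_b, params)
    if backend != "internal":
        raise ValueError(f"unknown backend {backend!r}")
    return internal_local_align(seq_a, seq_b, params)
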