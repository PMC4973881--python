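"""Seeded generator of GenBank record pairs with known duplicate labels.

Emulates the duplicate taxonomy the classifiers are built for:

* **ES** — the partner is a copy of the parent with point substitutions at
  a configured per-site rate and highly shared metadata;
* **EF** — the partner is a contiguous fragment (configured fraction) of
  the parent, lightly mutated, metadata shared;
* **NS** — the partner's sequence is drawn independently (no significant
  alignment survives), but metadata is shared: the duplicate is detectable
  only through description, literature, and submitter evidence;
* **DI** — two independent records;
* **DI_hard** — the partner carries a (near-)identical sequence but fully
  disjoint metadata, mimicking real distinct pairs of similar coding
  sequences for different proteins, the failure case of identity-threshold
  heuristics.

Records carry a description assembled from a shared vocabulary, literature
references with or without PubMed IDs, an optional direct-submission block
naming submitters, and (with configured probability) a single valid ORF as
CDS with its translation.  Everything derives from one integer seed;
generated corpora are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from seqdedup.labeling import PairLabel
from seqdedup.records import (
    CdsRegion,
    LiteratureRef,
    RecordPair,
    SequenceRecord,
    normalize_author,
    write_genbank,
)

__all__ = ["SynthConfig", "Corpus", "generate_corpus", "generate_separable_set"]

PAIR_CLASSES = ("ES", "EF", "NS", "DI", "DI_hard")

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults define the standard study conditions."""

    seed: int = 0
    n_pairs: dict[str, int] = field(
        default_factory=lambda: {"ES": 50, "EF": 50, "NS": 50, "DI": 100, "DI_hard": 50}
    )
    length_range: tuple[int, int] = (200, 500)
    es_mutation_rate: float = 0.005
    ef_fragment_range: tuple[float, float] = (0.3, 0.7)
    ef_mutation_rate: float = 0.002
    hard_mutation_rate: float = 0.002
    p_literature: float = 0.85
    p_submitter: float = 0.9
    p_shared_pmid: float = 0.8
    p_shared_submitter: float = 0.85
    p_description_perturb: float = 0.3
    cds_probability: float = 0.8
    vocab_size: int = 200
    author_pool_size: int = 60
    di_disjoint_metadata: bool = False
    organism: str = "Synthetica exempli"

    def __post_init__(self) -> None:
        for name in (
            "es_mutation_rate", "ef_mutation_rate", "hard_mutation_rate",
            "p_literature", "p_submitter", "p_shared_pmid",
            "p_shared_submitter", "p_description_perturb", "cds_probability",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        lo, hi = self.ef_fragment_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError(f"ef_fragment_range must lie inside (0, 1), got {self.ef_fragment_range}")
        if not 0 < self.length_range[0] <= self.length_range[1]:
            raise ValueError(f"invalid length_range {self.length_range}")
        if self.length_range[0] < 120:
            raise ValueError("minimum sequence length must be >= 120 to host an ORF")
        for cls, n in self.n_pairs.items():
            if cls not in PAIR_CLASSES:
                raise ValueError(f"unknown pair class {cls!r}; choose from {PAIR_CLASSES}")
            if n < 0:
                raise ValueError(f"n_pairs[{cls}] must be >= 0")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)


@dataclass
class Corpus:
    """A generated corpus: records, labelled pairs, and the ground truth."""

    records: list[SequenceRecord]
    pairs: list[RecordPair]
    truth: pd.DataFrame
    config: SynthConfig

    def write(self, out_dir: Union[str, Path]) -> dict[str, Path]:
        """Write GenBank records, the pair-label TSV, the ground-truth TSV,
        and a config echo; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "records": out / "records.gbk",
            "pairs": out / "pairs.tsv",
            "truth": out / "truth.tsv",
            "config": out / "config.json",
        }
        write_genbank(self.records, paths["records"])
        rows = []
        for pair in self.pairs:
            rows.append(
                {
                    "accession_a": pair.record_a.accession,
                    "accession_b": pair.record_b.accession,
                    "label": pair.label.binary,
                    "subtype": pair.label.subtype or "",
                }
            )
        pd.DataFrame(rows).to_csv(paths["pairs"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        paths["config"].write_text(self.config.to_json() + "\n")
        return paths


class _Generator:
    def __init__(self, config: SynthConfig) -> None:
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.counter = 0
        # two disjoint vocabulary halves: ordinary records draw from the
        # first; "hard" distinct partners draw from the second, so their
        # metadata shares nothing with the parent's
        vocab = self._make_vocab(config.vocab_size)
        half = config.vocab_size // 2
        self.vocab_main = vocab[:half]
        self.vocab_alt = vocab[half:]
        self.authors = self._make_authors(config.author_pool_size)
        half_a = config.author_pool_size // 2
        self.authors_main = self.authors[:half_a]
        self.authors_alt = self.authors[half_a:]

    def _make_vocab(self, n: int) -> list[str]:
        syllables = ["ba", "co", "dex", "fi", "gen", "ki", "lor", "mu", "nat",
                     "pro", "qua", "rin", "sol", "tu", "vex", "zym"]
        words = []
        while len(words) < n:
            k = self.rng.integers(2, 4)
            word = "".join(self.rng.choice(syllables, size=k))
            if word not in words:
                words.append(word)
        return words

    def _make_authors(self, n: int) -> list[str]:
        surnames = ["Ashby", "Bruno", "Chen", "Duarte", "Endo", "Farid",
                    "Gupta", "Horak", "Ivanov", "Jensen", "Kato", "Lund",
                    "Maier", "Novak", "Okoro", "Patel", "Quinn", "Rossi",
                    "Sato", "Tran", "Urban", "Varga", "Weiss", "Xu",
                    "Yamada", "Zhou"]
        out = []
        while len(out) < n:
            surname = str(self.rng.choice(surnames))
            initial = chr(ord("A") + int(self.rng.integers(0, 26)))
            # stored pre-normalized so written corpora round-trip exactly
            name = normalize_author(f"{surname},{initial}.")
            if name not in out:
                out.append(name)
        return out

    def _accession(self) -> str:
        self.counter += 1
        return f"SYN{self.counter:06d}"

    def _random_seq(self, length: int) -> str:
        return "".join(self.rng.choice(_BASES, size=length))

    def _mutate(self, seq: str, rate: float) -> str:
        if rate <= 0:
            return seq
        arr = np.array(list(seq))
        n_mut = self.rng.binomial(len(arr), rate)
        if n_mut == 0:
            return seq
        positions = self.rng.choice(len(arr), size=n_mut, replace=False)
        for pos in positions:
            choices = [b for b in "ACGT" if b != arr[pos]]
            arr[pos] = choices[int(self.rng.integers(0, 3))]
        return "".join(arr)

    def _make_orf(self, max_len: int) -> str:
        """A single ORF: ATG, non-stop codons, stop codon."""
        max_codons = (max_len - 6) // 3
        n_codons = int(self.rng.integers(20, min(60, max_codons) + 1))
        body = "".join(self.rng.choice(_CODONS, size=n_codons))
        stop = str(self.rng.choice(sorted(_STOPS)))
        return "ATG" + body + stop

    @staticmethod
    def _translate(cds_nt: str) -> str:
        protein = str(Seq(cds_nt).translate())
        return protein[:-1] if protein.endswith("*") else protein

    def _place_cds(self, sequence: str) -> tuple[str, CdsRegion]:
        orf = self._make_orf(len(sequence) - 20)
        start = int(self.rng.integers(0, len(sequence) - len(orf) + 1))
        end = start + len(orf)
        sequence = sequence[:start] + orf + sequence[end:]
        cds = CdsRegion(start=start, end=end, nucleotide_seq=orf,
                        translation=self._translate(orf))
        return sequence, cds

    def _description(self, alt: bool = False) -> str:
        vocab = self.vocab_alt if alt else self.vocab_main
        k = int(self.rng.integers(4, 8))
        tokens = list(self.rng.choice(vocab, size=k, replace=False))
        return " ".join(tokens) + " gene, complete cds"

    def _literature(self, alt: bool = False) -> Optional[LiteratureRef]:
        if self.rng.random() >= self.cfg.p_literature:
            return None
        pool = self.authors_alt if alt else self.authors_main
        authors = self.rng.choice(pool, size=int(self.rng.integers(2, 5)), replace=False)
        vocab = self.vocab_alt if alt else self.vocab_main
        title_tokens = self.rng.choice(vocab, size=5, replace=False)
        has_pmid = self.rng.random() < 0.8
        return LiteratureRef(
            pubmed_id=str(self.rng.integers(10**6, 10**8)) if has_pmid else None,
            journal=f"J. Synth. Biol. {int(self.rng.integers(1, 400))}",
            title=" ".join(title_tokens),
            authors=frozenset(str(a) for a in authors),
        )

    def _submitters(self, alt: bool = False) -> Optional[frozenset[str]]:
        if self.rng.random() >= self.cfg.p_submitter:
            return None
        pool = self.authors_alt if alt else self.authors_main
        names = self.rng.choice(pool, size=int(self.rng.integers(2, 4)), replace=False)
        return frozenset(str(n) for n in names)

    def random_record(self, alt_metadata: bool = False) -> SequenceRecord:
        length = int(self.rng.integers(*self.cfg.length_range, endpoint=True))
        sequence = self._random_seq(length)
        cds_regions: tuple[CdsRegion, ...] = ()
        if self.rng.random() < self.cfg.cds_probability:
            sequence, cds = self._place_cds(sequence)
            cds_regions = (cds,)
        lit = self._literature(alt=alt_metadata)
        return SequenceRecord(
            accession=self._accession(),
            organism=self.cfg.organism,
            description=self._description(alt=alt_metadata),
            sequence=sequence,
            references=(lit,) if lit else (),
            submitters=self._submitters(alt=alt_metadata),
            cds_regions=cds_regions,
        )

    def _shared_description(self, parent: SequenceRecord) -> str:
        desc = parent.description
        if self.rng.random() < self.cfg.p_description_perturb:
            tokens = desc.replace(", complete cds", "").split()
            if len(tokens) > 2:
                idx = int(self.rng.integers(0, len(tokens)))
                tokens[idx] = str(self.rng.choice(self.vocab_main))
                self.rng.shuffle(tokens)
                desc = " ".join(tokens) + ", complete cds"
        return desc

    def _shared_metadata(
        self, parent: SequenceRecord
    ) -> tuple[str, tuple[LiteratureRef, ...], Optional[frozenset[str]]]:
        description = self._shared_description(parent)
        if parent.references and self.rng.random() < self.cfg.p_shared_pmid:
            references = parent.references
        else:
            lit = self._literature()
            references = (lit,) if lit else ()
        if parent.submitters is not None and self.rng.random() < self.cfg.p_shared_submitter:
            submitters = parent.submitters
        else:
            submitters = self._submitters()
        return description, references, submitters

    def duplicate_partner(
        self, parent: SequenceRecord, kind: str
    ) -> tuple[SequenceRecord, dict]:
        description, references, submitters = self._shared_metadata(parent)
        draws: dict[str, object] = {}
        if kind == "ES":
            sequence = self._mutate(parent.sequence, self.cfg.es_mutation_rate)
            draws["n_substitutions"] = sum(
                a != b for a, b in zip(sequence, parent.sequence)
            )
            cds_regions = tuple(
                CdsRegion(
                    start=c.start, end=c.end,
                    nucleotide_seq=sequence[c.start:c.end],
                    translation=self._translate(sequence[c.start:c.end]),
                )
                for c in parent.cds_regions
            )
        elif kind == "EF":
            fraction = float(self.rng.uniform(*self.cfg.ef_fragment_range))
            frag_len = max(60, int(round(fraction * len(parent.sequence))))
            start = int(self.rng.integers(0, len(parent.sequence) - frag_len + 1))
            window = parent.sequence[start:start + frag_len]
            sequence = self._mutate(window, self.cfg.ef_mutation_rate)
            draws["fragment_fraction"] = frag_len / len(parent.sequence)
            draws["fragment_start"] = start
            cds_list = []
            for c in parent.cds_regions:
                if c.start >= start and c.end <= start + frag_len:
                    new_start, new_end = c.start - start, c.end - start
                    nt = sequence[new_start:new_end]
                    cds_list.append(
                        CdsRegion(start=new_start, end=new_end,
                                  nucleotide_seq=nt, translation=self._translate(nt))
                    )
            cds_regions = tuple(cds_list)
        elif kind == "NS":
            length = int(self.rng.integers(*self.cfg.length_range, endpoint=True))
            sequence = self._random_seq(length)
            cds_regions = ()
            if self.rng.random() < self.cfg.cds_probability:
                sequence, cds = self._place_cds(sequence)
                cds_regions = (cds,)
        else:
            raise ValueError(f"unknown duplicate kind {kind!r}")
        partner = SequenceRecord(
            accession=self._accession(),
            organism=parent.organism,
            description=description,
            sequence=sequence,
            references=references,
            submitters=submitters,
            cds_regions=cds_regions,
        )
        return partner, draws

    def hard_distinct_partner(self, parent: SequenceRecord) -> SequenceRecord:
        """Near-identical sequence, fully disjoint metadata; submitter
        information is withheld on the partner half of the time."""
        sequence = self._mutate(parent.sequence, self.cfg.hard_mutation_rate)
        cds_regions = tuple(
            CdsRegion(
                start=c.start, end=c.end,
                nucleotide_seq=sequence[c.start:c.end],
                translation=self._translate(sequence[c.start:c.end]),
            )
            for c in parent.cds_regions
        )
        lit = self._literature(alt=True)
        withhold = self.rng.random() < 0.5
        return SequenceRecord(
            accession=self._accession(),
            organism=parent.organism,
            description=self._description(alt=True),
            sequence=sequence,
            references=(lit,) if lit else (),
            submitters=None if withhold else self._submitters(alt=True),
            cds_regions=cds_regions,
        )

    def make_pair(self, kind: str) -> tuple[RecordPair, dict]:
        draws: dict[str, object] = {}
        if kind in ("ES", "EF", "NS"):
            parent = self.random_record()
            partner, draws = self.duplicate_partner(parent, kind)
            label = PairLabel("DU", kind)
            pair = RecordPair(parent, partner, label)
        elif kind == "DI":
            rec_a = self.random_record()
            rec_b = self.random_record(alt_metadata=self.cfg.di_disjoint_metadata)
            pair = RecordPair(rec_a, rec_b, PairLabel("DI"))
        elif kind == "DI_hard":
            parent = self.random_record()
            partner = self.hard_distinct_partner(parent)
            pair = RecordPair(parent, partner, PairLabel("DI"))
        else:
            raise ValueError(f"unknown pair class {kind!r}")
        return pair, draws


def generate_corpus(config: SynthConfig) -> Corpus:
    """Generate a labelled corpus for the configured per-class pair counts.

    Pair order is deterministic: classes in canonical order, each class
    block contiguous.  Duplicate/distinct balance is exactly what the
    configured counts request.
    """
    gen = _Generator(config)
    records: list[SequenceRecord] = []
    pairs: list[RecordPair] = []
    rows = []
    for kind in PAIR_CLASSES:
        for _ in range(config.n_pairs.get(kind, 0)):
            pair, draws = gen.make_pair(kind)
            records.extend([pair.record_a, pair.record_b])
            pairs.append(pair)
            rows.append(
                {
                    "accession_a": pair.record_a.accession,
                    "accession_b": pair.record_b.accession,
                    "pair_class": kind,
                    "label": pair.label.binary,
                    "subtype": pair.label.subtype or "",
                    "len_a": len(pair.record_a),
                    "len_b": len(pair.record_b),
                    **draws,
                }
            )
    truth = pd.DataFrame(rows)
    return Corpus(records=records, pairs=pairs, truth=truth, config=config)


def generate_separable_set(n: int, seed: int = 0) -> list[RecordPair]:
    """A corpus cleanly separable in feature space, for sanity checks.

    Half the pairs are exact-copy duplicates (ES at mutation rate 0 with
    fully shared metadata), half are distinct pairs with unrelated
    sequences and disjoint metadata.
    """
    if n < 100:
        raise ValueError(f"separable set needs n >= 100, got {n}")
    n_es = n // 2
    config = SynthConfig(
        seed=seed,
        n_pairs={"ES": n_es, "DI": n - n_es},
        es_mutation_rate=0.0,
        p_shared_pmid=1.0,
        p_shared_submitter=1.0,
        p_description_perturb=0.0,
        p_literature=1.0,
        p_submitter=1.0,
        di_disjoint_metadata=True,
    )
    return generate_corpus(config).pairs
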