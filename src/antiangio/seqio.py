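"""Reading, validating, transforming and splitting labeled peptide datasets.

Peptides are plain sequences over the 20 canonical amino acids.  Datasets pair
an ordered list of peptides with parallel binary labels (1 = anti-angiogenic,
0 = not).  FASTA I/O goes through Biopython; labels travel either as paired
positive/negative FASTA files or as a two-column TSV table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scales import AA_SET

logger = logging.getLogger(__name__)

__all__ = [
    "Peptide",
    "LabeledDataset",
    "read_fasta",
    "write_fasta",
    "make_labeled_dataset",
    "read_label_table",
    "write_label_table",
    "truncate_n_terminus",
    "stratified_split",
]


@dataclass(frozen=True)
class Peptide:
    """An identified amino-acid sequence over the canonical 20-letter alphabet."""

    id: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"peptide {self.id!r}: empty sequence")
        bad = set(self.sequence) - AA_SET
        if bad:
            raise ValueError(
                f"peptide {self.id!r}: non-canonical residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """Ordered peptides with parallel binary labels (1 = positive class)."""

    name: str
    peptides: list[Peptide]
    labels: np.ndarray  # int array parallel to peptides

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.peptides) != len(self.labels):
            raise ValueError("peptides and labels must be parallel")
        ids = [p.id for p in self.peptides]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate peptide ids in dataset {self.name!r}")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary (0/1)")

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    def subset(self, indices: Sequence[int], name: str | None = None) -> "LabeledDataset":
        return LabeledDataset(
            name or self.name,
            [self.peptides[i] for i in indices],
            self.labels[list(indices)],
        )


def read_fasta(path: str | Path, strict: bool = True) -> list[Peptide]:
    """Parse a FASTA file into peptides (order preserved, sequences upper-cased).

    In strict mode (default) a record with a residue outside the canonical
    alphabet raises ``ValueError`` naming the record.  In lenient mode such
    records are dropped with a logged warning (every encoder assumes the
    20-letter alphabet, so they cannot flow downstream).
    """
    path = Path(path)
    peptides: list[Peptide] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id == "" or len(rec.seq) == 0:
            raise ValueError(f"{path}: malformed/empty FASTA record {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - AA_SET
        if bad:
            if strict:
                raise ValueError(
                    f"{path}: record {rec.id!r} has non-canonical residue(s) "
                    f"{sorted(bad)}"
                )
            logger.warning(
                "dropping record %r: non-canonical residue(s) %s", rec.id, sorted(bad)
            )
            continue
        peptides.append(Peptide(rec.id, seq))
    return peptides


def write_fasta(path: str | Path, peptides: Iterable[Peptide]) -> None:
    """Write peptides as FASTA, wrapped at 60 columns."""
    records = [SeqRecord(Seq(p.sequence), id=p.id, description="") for p in peptides]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def make_labeled_dataset(
    positives: Sequence[Peptide],
    negatives: Sequence[Peptide],
    name: str = "dataset",
) -> LabeledDataset:
    """Combine positive and negative peptides into one labeled dataset.

    Labels are 1 for positives then 0 for negatives, order preserved.  An id
    collision between the two files is resolved by prefixing ``pos_``/``neg_``.
    """
    if not positives and not negatives:
        raise ValueError("both positive and negative inputs are empty")
    pos_ids = {p.id for p in positives}
    neg_ids = {p.id for p in negatives}
    if pos_ids & neg_ids:
        positives = [Peptide(f"pos_{p.id}", p.sequence) for p in positives]
        negatives = [Peptide(f"neg_{p.id}", p.sequence) for p in negatives]
    peptides = list(positives) + list(negatives)
    labels = np.concatenate([np.ones(len(positives), int), np.zeros(len(negatives), int)])
    return LabeledDataset(name, peptides, labels)


def read_label_table(fasta_path: str | Path, table_path: str | Path,
                     name: str = "dataset", strict: bool = True) -> LabeledDataset:
    """Build a dataset from one FASTA plus an ``id<TAB>label`` table."""
    peptides = read_fasta(fasta_path, strict=strict)
    labels = {}
    for lineno, line in enumerate(Path(table_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        try:
            pid, lab = line.split("\t")
            labels[pid] = int(lab)
        except ValueError as exc:
            raise ValueError(f"{table_path}:{lineno}: malformed label line") from exc
    missing = [p.id for p in peptides if p.id not in labels]
    if missing:
        raise ValueError(f"{table_path}: no label for id(s) {missing[:5]}")
    return LabeledDataset(name, peptides, np.array([labels[p.id] for p in peptides]))


def write_label_table(path: str | Path, dataset: LabeledDataset) -> None:
    with open(path, "w") as fh:
        for p, lab in zip(dataset.peptides, dataset.labels):
            fh.write(f"{p.id}\t{int(lab)}\n")


def truncate_n_terminus(dataset: LabeledDataset, n: int = 15) -> LabeledDataset:
    """Replace every sequence by its first ``min(n, length)`` residues.

    Mirrors the construction of N-terminus datasets, where classification uses
    only the first 15 residues from the amino end.  Idempotent for fixed n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    peptides = [Peptide(p.id, p.sequence[: min(n, len(p))]) for p in dataset.peptides]
    return LabeledDataset(dataset.name, peptides, dataset.labels.copy())


def stratified_split(
    dataset: LabeledDataset, fraction: float = 0.8, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Split into development/test sets preserving class proportions.

    Per class, the development set receives ``ceil(fraction * class_size)``
    members (fractional remainders go to the development set); membership is a
    seeded uniform draw, so the split is deterministic given the seed.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    dev_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (0, 1):
        members = np.flatnonzero(dataset.labels == cls)
        if len(members) < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        n_dev = math.ceil(fraction * len(members))
        perm = rng.permutation(members)
        dev_idx.extend(perm[:n_dev])
        test_idx.extend(perm[n_dev:])
    dev_idx.sort()
    test_idx.sort()
    return (
        dataset.subset(dev_idx, f"{dataset.name}_dev"),
        dataset.subset(test_idx, f"{dataset.name}_test"),
    )
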