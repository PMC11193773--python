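"""Synthetic labeled peptide datasets and feature matrices with known truth.

The peptide generator emulates the structure of curated anti-angiogenic
peptide benchmarks: two balanced classes of ~100 peptides, lengths 10-50 (or
exactly 15 for N-terminus-style data), with class-biased residue usage —
C, P, R, S, W enriched in positives and A, E, I, L, V in negatives.  Residues
are drawn i.i.d. from class-specific multinomials (a uniform base composition
re-weighted by the enrichment factor and renormalized), so real-sequence
features such as motifs, ordering or shared evolutionary history are *not*
modelled; what the generator supports is exercising and validating every
pipeline stage against a known ground truth.

The feature-matrix generator supports selection-recovery experiments: a small
number of informative columns carry a class mean shift (in units of the unit
noise), the rest are pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .scales import AA_LIST
from .seqio import LabeledDataset, Peptide

__all__ = ["GeneratorConfig", "fulllength_config", "nterm15_config",
           "generate_peptide_dataset", "generate_feature_matrix"]


@dataclass(frozen=True)
class GeneratorConfig:
    n_pos: int = 100
    n_neg: int = 100
    length_min: int = 10
    length_max: int = 50
    pos_bias: str = "CPRSW"
    neg_bias: str = "AEILV"
    pos_factor: float = 5.0
    neg_factor: float = 5.0
    seed: int = 0

    def class_weights(self, positive: bool) -> np.ndarray:
        """Residue sampling probabilities for one class (uniform base
        re-weighted by the bias factor on the class's enriched residues)."""
        bias, factor = ((self.pos_bias, self.pos_factor) if positive
                        else (self.neg_bias, self.neg_factor))
        if factor <= 0:
            raise ValueError("enrichment factor must be > 0")
        w = np.array([factor if aa in bias else 1.0 for aa in AA_LIST])
        return w / w.sum()


def fulllength_config(**kw) -> GeneratorConfig:
    """Preset mimicking full-length benchmark sets (lengths 10-50)."""
    return replace(GeneratorConfig(), **kw)


def nterm15_config(**kw) -> GeneratorConfig:
    """Preset mimicking N-terminus benchmark sets (every peptide a 15-mer)."""
    return replace(GeneratorConfig(length_min=15, length_max=15), **kw)


def generate_peptide_dataset(cfg: GeneratorConfig,
                             name: str = "synthetic") -> LabeledDataset:
    """Draw a labeled dataset from the configured class multinomials."""
    if cfg.n_pos < 1 or cfg.n_neg < 1:
        raise ValueError("class counts must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    aa = np.array(AA_LIST)

    def draw(n, positive, prefix):
        probs = cfg.class_weights(positive)
        peps = []
        for i in range(n):
            L = rng.integers(cfg.length_min, cfg.length_max + 1)
            seq = "".join(rng.choice(aa, size=L, p=probs))
            peps.append(Peptide(f"{prefix}{i + 1}", seq))
        return peps

    pos = draw(cfg.n_pos, True, "pos")
    neg = draw(cfg.n_neg, False, "neg")
    labels = np.concatenate([np.ones(cfg.n_pos, int), np.zeros(cfg.n_neg, int)])
    return LabeledDataset(name, pos + neg, labels)


def generate_feature_matrix(n_samples: int = 200, n_informative: int = 10,
                            n_noise: int = 490, effect: float = 3.0,
                            seed: int = 0):
    """Gaussian feature matrix with a known informative subset.

    Informative columns get a between-class mean shift of ``effect`` (noise is
    unit variance); noise columns are N(0, 1) for both classes.  Returns
    ``(matrix, labels, informative_names)``; labels are balanced.
    """
    if n_informative < 1:
        raise ValueError("n_informative must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.zeros(n_samples, int)
    y[: n_samples // 2] = 1
    rng.shuffle(y)
    p = n_informative + n_noise
    X = rng.standard_normal((n_samples, p))
    X[:, :n_informative] += effect * y[:, None]
    names = ([f"inf{i + 1}" for i in range(n_informative)]
             + [f"noise{i + 1}" for i in range(n_noise)])
    df = pd.DataFrame(X, index=[f"s{i + 1}" for i in range(n_samples)], columns=names)
    return df, y, names[:n_informative]
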