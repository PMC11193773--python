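"""Peptide sequence descriptors: a registry of feature encoders.

Every encoder turns one sequence into a fixed-length named numeric vector.
The default registry assembles 58 descriptor types totalling exactly 4335
values per peptide: the classical composition families (AAC, DPC, grouped and
k-spaced variants, pseudo amino-acid composition, CTD, conjoint triad, DDE,
entropies, residue distance distribution, length) plus physicochemical-scale
autocorrelation descriptors (z-scales, membrane-insertion and pharmacophore
composites, and 37 single-scale tables).  The full layout, including the
pinned free parameters, is written out by :func:`write_manifest`.

Composition-style encoders are normalized so each block sums to one.  Terms a
sequence is too short to support (a gap or lag reaching past the last residue)
are set to zero with a logged warning instead of failing mid-pipeline, which
is what keeps 15-mer N-terminus datasets flowing through the same registry.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import scales
from .scales import (AA_LIST, ALPHABET, CODON_COUNTS, CTD_PROPERTIES,
                     CTRIAD_CLASS_OF, GROUP5_OF, GROUPS5, MULTI_SCALES,
                     SCALES_1D, GLOBAL_MEAN_SCALES)
from .seqio import LabeledDataset, Peptide

logger = logging.getLogger(__name__)
_warned: set[str] = set()


def _warn_once(key: str, msg: str, *args) -> None:
    if key not in _warned:
        _warned.add(key)
        logger.warning(msg, *args)


def _seq(p) -> str:
    return p.sequence if isinstance(p, Peptide) else str(p)


# --------------------------------------------------------------------------
# composition families
# --------------------------------------------------------------------------

def encode_aac(p) -> np.ndarray:
    """Amino-acid composition: 20 residue frequencies, summing to 1."""
    s = _seq(p)
    counts = np.array([s.count(aa) for aa in AA_LIST], float)
    return counts / len(s)


_DIPEPTIDES = tuple(a + b for a in AA_LIST for b in AA_LIST)


def encode_dpc(p) -> np.ndarray:
    """Dipeptide composition: 400 pair frequencies over the L-1 adjacent pairs."""
    s = _seq(p)
    out = np.zeros(400)
    if len(s) < 2:
        _warn_once("DPC", "DPC: sequence of length 1, returning zeros")
        return out
    idx = {pair: i for i, pair in enumerate(_DIPEPTIDES)}
    for a, b in zip(s, s[1:]):
        out[idx[a + b]] += 1
    return out / (len(s) - 1)


_GROUP_KEYS = tuple(GROUPS5)
_GROUP_PAIRS = tuple((g, h) for g in _GROUP_KEYS for h in _GROUP_KEYS)


def encode_gaac(p) -> np.ndarray:
    """Grouped amino-acid composition over the 5 physicochemical groups."""
    s = _seq(p)
    counts = np.zeros(5)
    for aa in s:
        counts[_GROUP_KEYS.index(GROUP5_OF[aa])] += 1
    return counts / len(s)


def encode_gdpc(p) -> np.ndarray:
    """Grouped dipeptide composition: 25 group-pair frequencies."""
    s = _seq(p)
    out = np.zeros(25)
    if len(s) < 2:
        _warn_once("GDPC", "GDPC: sequence of length 1, returning zeros")
        return out
    idx = {pair: i for i, pair in enumerate(_GROUP_PAIRS)}
    for a, b in zip(s, s[1:]):
        out[idx[(GROUP5_OF[a], GROUP5_OF[b])]] += 1
    return out / (len(s) - 1)


def encode_cksaap(p, kmax: int = 4) -> np.ndarray:
    """Composition of k-spaced residue pairs for gaps k = 0..kmax.

    Block k holds the frequencies of pairs (s[i], s[i+k+1]) over the L-k-1
    admissible positions; each block sums to 1 when the sequence supports it.
    """
    s = _seq(p)
    idx = {pair: i for i, pair in enumerate(_DIPEPTIDES)}
    blocks = []
    for k in range(kmax + 1):
        block = np.zeros(400)
        n = len(s) - k - 1
        if n < 1:
            _warn_once(f"CKSAAP.k{k}", "CKSAAP: sequence too short for gap %d", k)
        else:
            for i in range(n):
                block[idx[s[i] + s[i + k + 1]]] += 1
            block /= n
        blocks.append(block)
    return np.concatenate(blocks)


def encode_cksaagp(p, kmax: int = 5) -> np.ndarray:
    """Composition of k-spaced residue-group pairs (25 pairs x kmax+1 gaps)."""
    s = _seq(p)
    idx = {pair: i for i, pair in enumerate(_GROUP_PAIRS)}
    blocks = []
    for k in range(kmax + 1):
        block = np.zeros(25)
        n = len(s) - k - 1
        if n < 1:
            _warn_once(f"CKSAAGP.k{k}", "CKSAAGP: sequence too short for gap %d", k)
        else:
            for i in range(n):
                block[idx[(GROUP5_OF[s[i]], GROUP5_OF[s[i + k + 1]])]] += 1
            block /= n
        blocks.append(block)
    return np.concatenate(blocks)


# Chou-style standardization of the two amphiphilic property scales.
_APAAC_H1 = scales.standardized(scales.KYTE_DOOLITTLE)   # hydrophobicity
_APAAC_H2 = scales.standardized(scales.HOPP_WOODS)       # hydrophilicity


def encode_apaac(p, lam: int = 5, w: float = 0.05) -> np.ndarray:
    """Amphiphilic pseudo amino-acid composition (20 + 2*lam values).

    The first 20 entries are residue frequencies; the remaining 2*lam entries
    are sequence-order correlation factors of the standardized hydrophobicity
    and hydrophilicity scales at lags 1..lam, weighted by ``w``.  The whole
    vector is normalized to sum to 1.
    """
    s = _seq(p)
    L = len(s)
    if L <= lam:
        raise ValueError(f"APAAC requires length > lambda ({L} <= {lam})")
    h1 = np.array([_APAAC_H1[aa][0] for aa in s])
    h2 = np.array([_APAAC_H2[aa][0] for aa in s])
    taus = []
    for j in range(1, lam + 1):
        taus.append(np.mean(h1[:-j] * h1[j:]))
        taus.append(np.mean(h2[:-j] * h2[j:]))
    taus = np.array(taus)
    freqs = encode_aac(s)
    denom = 1.0 + w * taus.sum()
    return np.concatenate([freqs / denom, w * taus / denom])


def encode_sep(p) -> np.ndarray:
    """Shannon entropy of the whole-sequence residue composition (bits)."""
    return np.array([encode_ser(p).sum()])


def encode_ser(p) -> np.ndarray:
    """Per-residue Shannon entropy contributions -p_a log2 p_a (0 if absent)."""
    freqs = encode_aac(p)
    out = np.zeros(20)
    nz = freqs > 0
    out[nz] = -freqs[nz] * np.log2(freqs[nz])
    return out


# --------------------------------------------------------------------------
# CTD (composition / transition / distribution)
# --------------------------------------------------------------------------

def _ctd_group_seq(s: str, prop: str) -> np.ndarray:
    groups = CTD_PROPERTIES[prop]
    lookup = {aa: gi for gi, members in enumerate(groups) for aa in members}
    return np.array([lookup[aa] for aa in s])


def encode_ctdc(p) -> np.ndarray:
    """CTD composition: per property, the 3 group frequencies (39 values)."""
    s = _seq(p)
    out = []
    for prop in CTD_PROPERTIES:
        g = _ctd_group_seq(s, prop)
        out.extend((g == gi).mean() for gi in range(3))
    return np.array(out)


def encode_ctdt(p) -> np.ndarray:
    """CTD transition: per property, frequencies of adjacent group changes
    (pairs 1-2, 1-3, 2-3; 39 values)."""
    s = _seq(p)
    out = []
    for prop in CTD_PROPERTIES:
        g = _ctd_group_seq(s, prop)
        n = len(s) - 1
        for gi, gj in ((0, 1), (0, 2), (1, 2)):
            if n < 1:
                out.append(0.0)
            else:
                trans = np.sum(((g[:-1] == gi) & (g[1:] == gj))
                               | ((g[:-1] == gj) & (g[1:] == gi)))
                out.append(trans / n)
    return np.array(out)


def encode_ctdd(p) -> np.ndarray:
    """CTD distribution: per property and group, the relative sequence
    positions of the first/25%/50%/75%/last occurrence (195 values, in [0,1];
    0 when the group is absent)."""
    s = _seq(p)
    L = len(s)
    out = []
    for prop in CTD_PROPERTIES:
        g = _ctd_group_seq(s, prop)
        for gi in range(3):
            pos = np.flatnonzero(g == gi) + 1  # 1-based
            if len(pos) == 0:
                out.extend([0.0] * 5)
                continue
            for q in (0, 25, 50, 75, 100):
                k = max(1, math.ceil(q / 100 * len(pos)))
                out.append(pos[k - 1] / L)
    return np.array(out)


# --------------------------------------------------------------------------
# conjoint triad, DDE, DDR
# --------------------------------------------------------------------------

def encode_ctriad(p) -> np.ndarray:
    """Conjoint triad: min-max-normalized counts of 3-mers over the 7-class
    alphabet (343 values in [0,1]); all-zero for sequences shorter than 3."""
    s = _seq(p)
    out = np.zeros(343)
    if len(s) < 3:
        _warn_once("CTriad", "CTriad: sequence shorter than 3, returning zeros")
        return out
    for i in range(len(s) - 2):
        c1, c2, c3 = (CTRIAD_CLASS_OF[aa] - 1 for aa in s[i:i + 3])
        out[c1 * 49 + c2 * 7 + c3] += 1
    mn, mx = out.min(), out.max()
    if mx > 0:
        out = (out - mn) / mx
    return out


def encode_dde(p) -> np.ndarray:
    """Dipeptide deviation from expected mean.

    DDE(ab) = (Dc(ab) - Tm(ab)) / sqrt(Tv(ab)), with Dc the observed dipeptide
    composition, Tm(ab) = (Ca/61)(Cb/61) the expectation under standard-code
    codon usage, and Tv(ab) = Tm(1 - Tm)/(L - 1).
    """
    s = _seq(p)
    L = len(s)
    if L < 2:
        raise ValueError("DDE requires length >= 2")
    dc = encode_dpc(s)
    tm = np.array([
        (CODON_COUNTS[a] / 61.0) * (CODON_COUNTS[b] / 61.0)
        for a in AA_LIST for b in AA_LIST
    ])
    tv = tm * (1 - tm) / (L - 1)
    return (dc - tm) / np.sqrt(tv)


def encode_ddr(p) -> np.ndarray:
    """Distance distribution of residues: per residue type, the mean gap
    between consecutive occurrences divided by L (0 if the residue occurs
    fewer than twice)."""
    s = _seq(p)
    L = len(s)
    out = np.zeros(20)
    for i, aa in enumerate(AA_LIST):
        pos = [j for j, c in enumerate(s) if c == aa]
        if len(pos) >= 2:
            out[i] = np.mean(np.diff(pos)) / L
    return out


def encode_length(p) -> np.ndarray:
    return np.array([float(len(_seq(p)))])


# --------------------------------------------------------------------------
# physicochemical-scale autocorrelation
# --------------------------------------------------------------------------

def encode_scale_descriptor(p, table: Mapping[str, Sequence[float] | float],
                            nlag: int, include_mean: bool = False,
                            name: str = "scale") -> np.ndarray:
    """Autocorrelation descriptor of a per-residue physicochemical table.

    The table (d dimensions) is standardized over the 20 residues; feature
    (dim i, lag l) is the mean product of the standardized values at sequence
    separation l, for l = 1..nlag.  Lags the sequence cannot support are 0.
    ``include_mean`` prepends the raw per-dimension sequence mean (the classic
    GRAVY-style global average).  Output length: d * nlag (+d with the mean).
    """
    s = _seq(p)
    std = scales.standardized(table)
    V = np.array([std[aa] for aa in s])           # L x d, standardized
    d = V.shape[1]
    out = []
    if include_mean:
        raw = np.array([np.atleast_1d(table[aa]) for aa in s], dtype=float)
        out.extend(raw.mean(axis=0))
    for dim in range(d):
        v = V[:, dim]
        for lag in range(1, nlag + 1):
            if lag >= len(s):
                _warn_once(f"{name}.lag{lag}",
                           "%s: lag %d exceeds sequence length, term set to 0",
                           name, lag)
                out.append(0.0)
            else:
                out.append(float(np.mean(v[:-lag] * v[lag:])))
    return np.array(out)


# --------------------------------------------------------------------------
# registry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptorSpec:
    """One descriptor type: a name, its parameters, stable feature names, and
    the encoding function.  ``size`` is the declared output length; encoding
    any valid peptide yields exactly ``size`` values."""

    name: str
    params: dict
    feature_names: tuple[str, ...]
    encoder: Callable[[str], np.ndarray] = field(repr=False)

    @property
    def size(self) -> int:
        return len(self.feature_names)

    def encode(self, p) -> np.ndarray:
        out = np.asarray(self.encoder(_seq(p)), dtype=float)
        if out.shape != (self.size,):
            raise ValueError(
                f"{self.name}: encoder returned {out.shape}, declared size {self.size}"
            )
        return out


class EncoderRegistry:
    """Ordered collection of descriptor specs with unique names."""

    def __init__(self, specs: Iterable[DescriptorSpec]):
        self.specs = list(specs)
        names = [sp.name for sp in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate descriptor names in registry")
        for sp in self.specs:
            if sp.size < 1:
                raise ValueError(f"{sp.name}: size must be >= 1")

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    @property
    def total_size(self) -> int:
        return sum(sp.size for sp in self.specs)

    @property
    def feature_names(self) -> list[str]:
        return [fn for sp in self.specs for fn in sp.feature_names]

    def subset(self, names: Sequence[str]) -> "EncoderRegistry":
        by_name = {sp.name: sp for sp in self.specs}
        missing = [n for n in names if n not in by_name]
        if missing:
            raise KeyError(f"unknown descriptor type(s): {missing}")
        return EncoderRegistry([by_name[n] for n in names])

    def hash(self) -> str:
        payload = [(sp.name, sorted(sp.params.items()), sp.size) for sp in self.specs]
        return hashlib.sha256(repr(payload).encode()).hexdigest()[:16]

    def write_manifest(self, path: str | Path) -> None:
        """Write a TSV manifest: one line per spec (name, size, params JSON)."""
        with open(path, "w") as fh:
            fh.write(f"# registry hash: {self.hash()}\n")
            fh.write("name\tsize\tparams\n")
            for sp in self.specs:
                fh.write(f"{sp.name}\t{sp.size}\t{json.dumps(sp.params, sort_keys=True)}\n")


def _names(prefix: str, subnames: Iterable[str]) -> tuple[str, ...]:
    return tuple(f"{prefix}.{s}" for s in subnames)


def default_registry() -> EncoderRegistry:
    """The default 58-type / 4335-value descriptor registry."""
    specs: list[DescriptorSpec] = []
    add = specs.append

    add(DescriptorSpec("LEN", {}, ("LEN.length",), encode_length))
    add(DescriptorSpec("AAC", {}, _names("AAC", AA_LIST), encode_aac))
    add(DescriptorSpec("DPC", {}, _names("DPC", _DIPEPTIDES), encode_dpc))
    add(DescriptorSpec("GAAC", {}, _names("GAAC", _GROUP_KEYS), encode_gaac))
    add(DescriptorSpec("GDPC", {}, _names("GDPC", (f"{g}{h}" for g, h in _GROUP_PAIRS)),
                       encode_gdpc))
    kmax = 4
    add(DescriptorSpec(
        "CKSAAP", {"kmax": kmax},
        _names("CKSAAP", (f"k{k}.{pair}" for k in range(kmax + 1) for pair in _DIPEPTIDES)),
        lambda s, k=kmax: encode_cksaap(s, kmax=k)))
    add(DescriptorSpec(
        "CKSAAGP", {"kmax": 5},
        _names("CKSAAGP", (f"k{k}.{g}{h}" for k in range(6) for g, h in _GROUP_PAIRS)),
        lambda s: encode_cksaagp(s, kmax=5)))
    lam, w = 5, 0.05
    apaac_names = list(AA_LIST) + [
        f"{prop}.lag{j}" for j in range(1, lam + 1) for prop in ("hphob", "hphil")
    ]
    add(DescriptorSpec("APAAC", {"lambda": lam, "w": w}, _names("APAAC", apaac_names),
                       lambda s: encode_apaac(s, lam=lam, w=w)))
    add(DescriptorSpec("SEP", {}, ("SEP.entropy",), encode_sep))
    add(DescriptorSpec("SER", {}, _names("SER", AA_LIST), encode_ser))
    add(DescriptorSpec("CTDC", {}, _names(
        "CTDC", (f"{prop}.g{g+1}" for prop in CTD_PROPERTIES for g in range(3))),
        encode_ctdc))
    add(DescriptorSpec("CTDT", {}, _names(
        "CTDT", (f"{prop}.{t}" for prop in CTD_PROPERTIES for t in ("g1g2", "g1g3", "g2g3"))),
        encode_ctdt))
    add(DescriptorSpec("CTDD", {}, _names(
        "CTDD", (f"{prop}.g{g+1}.p{q}" for prop in CTD_PROPERTIES
                 for g in range(3) for q in (0, 25, 50, 75, 100))),
        encode_ctdd))
    add(DescriptorSpec("CTriad", {}, _names(
        "CTriad", (f"{a}{b}{c}" for a in range(1, 8) for b in range(1, 8)
                   for c in range(1, 8))),
        encode_ctriad))
    add(DescriptorSpec("DDE", {}, _names("DDE", _DIPEPTIDES), encode_dde))
    add(DescriptorSpec("DDR", {}, _names("DDR", AA_LIST), encode_ddr))

    # multidimensional scale descriptors; lag layouts pinned to fixed sizes
    multi_layout = {"Ez": 10, "Z3": 10, "Z5": 15, "Cougar": 5, "ABHPRK": 15}
    for sname in ("Ez", "Z3", "Z5", "Cougar", "ABHPRK"):
        dims, table = MULTI_SCALES[sname]
        nlag = multi_layout[sname]
        names = _names(sname, (f"{d}.lag{l}" for d in dims for l in range(1, nlag + 1)))
        add(DescriptorSpec(sname, {"nlag": nlag, "dims": len(dims)}, names,
                           lambda s, t=table, n=nlag, nm=sname:
                           encode_scale_descriptor(s, t, nlag=n, name=nm)))

    # 37 single-scale autocorrelation descriptors (lags 1..10; the classic
    # hydropathy/surface scales also expose the raw global mean)
    for sname in sorted(SCALES_1D):
        table = SCALES_1D[sname]
        inc = sname in GLOBAL_MEAN_SCALES
        sub = (["mean"] if inc else []) + [f"lag{l}" for l in range(1, 11)]
        add(DescriptorSpec(sname, {"nlag": 10, "mean": inc}, _names(sname, sub),
                           lambda s, t=table, i=inc, nm=sname:
                           encode_scale_descriptor(s, t, nlag=10, include_mean=i, name=nm)))

    return EncoderRegistry(specs)


def encode_all(dataset: LabeledDataset, registry: EncoderRegistry) -> pd.DataFrame:
    """Encode every peptide; returns a samples x features DataFrame.

    Row index is the peptide id; columns are "<TYPE>.<feature>" in registry
    order; ``df.attrs['registry_hash']`` records provenance.
    """
    rows = []
    for pep in dataset.peptides:
        try:
            rows.append(np.concatenate([sp.encode(pep) for sp in registry]))
        except Exception as exc:
            raise type(exc)(f"while encoding peptide {pep.id!r}: {exc}") from exc
    df = pd.DataFrame(rows, index=dataset.ids, columns=registry.feature_names)
    if df.isna().any().any():
        raise ValueError("encoding produced missing values")
    df.attrs["registry_hash"] = registry.hash()
    return df
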