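"""Descriptor encoders: worked examples, counting oracles, and registry
envelope invariants."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from antiangio import scales
from antiangio.encoders import (DescriptorSpec, EncoderRegistry, default_registry,
                                encode_aac, encode_all, encode_apaac,
                                encode_cksaagp, encode_cksaap, encode_ctdc,
                                encode_ctdd, encode_ctdt, encode_ctriad,
                                encode_dde, encode_ddr, encode_dpc, encode_gaac,
                                encode_gdpc, encode_length,
                                encode_scale_descriptor, encode_sep, encode_ser)
from antiangio.scales import AA_LIST, GROUPS5
from antiangio.seqio import LabeledDataset, Peptide

peptides = st.text(alphabet=scales.ALPHABET, min_size=5, max_size=12)


# ---------------------------------------------------------------------------
# composition examples
# ---------------------------------------------------------------------------

def test_aac_examples():
    v = dict(zip(AA_LIST, encode_aac("AAAA")))
    assert v["A"] == 1.0 and sum(v.values()) == 1.0
    v = dict(zip(AA_LIST, encode_aac("ACDC")))
    assert v["A"] == 0.25 and v["C"] == 0.5 and v["D"] == 0.25


def test_dpc_examples():
    pairs = [a + b for a in AA_LIST for b in AA_LIST]
    v = dict(zip(pairs, encode_dpc("AAA")))
    assert v["AA"] == 1.0
    v = dict(zip(pairs, encode_dpc("ACAC")))
    assert v["AC"] == pytest.approx(2 / 3) and v["CA"] == pytest.approx(1 / 3)


def test_dpc_single_residue_is_all_zero():
    assert encode_dpc("A").sum() == 0.0


def test_gaac_group_membership():
    v = dict(zip(GROUPS5, encode_gaac("GAVLMI")))
    assert v["ali"] == 1.0


def test_gdpc_charged_pair():
    keys = [f"{g}{h}" for g in GROUPS5 for h in GROUPS5]
    v = dict(zip(keys, encode_gdpc("KD")))
    assert v["posneg"] == 1.0


def test_cksaap_gap_blocks():
    out = encode_cksaap("AA", kmax=0)
    assert out[0] == 1.0 and out.sum() == 1.0  # pair AA at gap 0
    out = encode_cksaap("ACA", kmax=1)
    k1 = dict(zip([a + b for a in AA_LIST for b in AA_LIST], out[400:]))
    assert k1["AA"] == 1.0


def test_cksaagp_default_size_and_first_block():
    out = encode_cksaagp("AA")
    assert out.shape == (150,)
    keys = [f"k{k}.{g}{h}" for k in range(6) for g in GROUPS5 for h in GROUPS5]
    v = dict(zip(keys, out))
    assert v["k0.aliali"] == 1.0


@given(peptides)
def test_composition_blocks_sum_to_one(seq):
    assert encode_aac(seq).sum() == pytest.approx(1.0, abs=1e-12)
    assert encode_dpc(seq).sum() == pytest.approx(1.0, abs=1e-12)
    assert encode_gaac(seq).sum() == pytest.approx(1.0, abs=1e-12)
    assert encode_gdpc(seq).sum() == pytest.approx(1.0, abs=1e-12)
    out = encode_cksaap(seq, kmax=2)
    for k in range(3):
        block = out[400 * k: 400 * (k + 1)]
        if len(seq) > k + 1:
            assert block.sum() == pytest.approx(1.0, abs=1e-12)
    assert (out >= 0).all()


@given(peptides)
def test_aac_dpc_match_brute_force_counter(seq):
    counts = Counter(seq)
    expected = np.array([counts[aa] / len(seq) for aa in AA_LIST])
    assert np.allclose(encode_aac(seq), expected)
    pair_counts = Counter(seq[i: i + 2] for i in range(len(seq) - 1))
    pairs = [a + b for a in AA_LIST for b in AA_LIST]
    expected = np.array([pair_counts[p] / (len(seq) - 1) for p in pairs])
    assert np.allclose(encode_dpc(seq), expected)


@given(peptides, st.integers(0, 3))
def test_cksaap_matches_brute_force_pair_enumeration(seq, k):
    out = encode_cksaap(seq, kmax=k)[400 * k: 400 * (k + 1)]
    pairs = [a + b for a in AA_LIST for b in AA_LIST]
    n = len(seq) - k - 1
    brute = Counter(seq[i] + seq[i + k + 1] for i in range(n))
    expected = np.array([brute[p] / n for p in pairs]) if n > 0 else np.zeros(400)
    assert np.allclose(out, expected)


# ---------------------------------------------------------------------------
# pseudo amino-acid composition
# ---------------------------------------------------------------------------

def test_apaac_length_and_normalization():
    out = encode_apaac("ACDEFGHIKL", lam=3)
    assert out.shape == (26,)
    assert out.sum() == pytest.approx(1.0, abs=1e-12)


def test_apaac_rejects_short_sequence():
    with pytest.raises(ValueError, match="lambda"):
        encode_apaac("ACD", lam=3)


def test_apaac_homopolymer_matches_stepwise_oracle():
    # Independent step-by-step evaluation on "AAAAA", lambda=1, w=0.05.
    h1 = scales.standardized(scales.KYTE_DOOLITTLE)["A"][0]
    h2 = scales.standardized(scales.HOPP_WOODS)["A"][0]
    tau1 = h1 * h1          # all products identical on a homopolymer
    tau2 = h2 * h2
    w = 0.05
    denom = 1.0 + w * (tau1 + tau2)
    expected = np.zeros(22)
    expected[0] = 1.0 / denom            # frequency of A
    expected[20] = w * tau1 / denom
    expected[21] = w * tau2 / denom
    assert np.allclose(encode_apaac("AAAAA", lam=1, w=w), expected)


# ---------------------------------------------------------------------------
# entropies
# ---------------------------------------------------------------------------

def test_sep_homopolymer_is_zero():
    assert encode_sep("AAAA")[0] == 0.0


def test_sep_uniform_composition_hits_log2_20():
    assert encode_sep(scales.ALPHABET)[0] == pytest.approx(math.log2(20))


@given(peptides)
def test_sep_equals_sum_of_ser(seq):
    assert encode_sep(seq)[0] == pytest.approx(encode_ser(seq).sum())


# ---------------------------------------------------------------------------
# CTD
# ---------------------------------------------------------------------------

def test_ctdc_homopolymer_and_triplet_sums():
    out = encode_ctdc("AAAA")
    assert out.shape == (39,)
    # per property exactly one group holds A, with composition 1
    for i in range(13):
        triplet = out[3 * i: 3 * i + 3]
        assert triplet.sum() == pytest.approx(1.0)
        assert triplet.max() == 1.0
    assert encode_ctdt("AAAA").sum() == 0.0  # no transitions on homopolymer


@given(peptides)
def test_ctdc_triplets_always_sum_to_one(seq):
    out = encode_ctdc(seq)
    for i in range(13):
        assert out[3 * i: 3 * i + 3].sum() == pytest.approx(1.0)


def test_ctdd_positions_for_known_sequence():
    # hydrophobicity groups: polar RKEDQN / neutral GASTPHY / hydrophobic CLVIMFW
    out = dict(zip(
        (f"{prop}.g{g + 1}.p{q}" for prop in scales.CTD_PROPERTIES
         for g in range(3) for q in (0, 25, 50, 75, 100)),
        encode_ctdd("RGGR")))
    assert out["hydrophobicity.g1.p0"] == pytest.approx(1 / 4)    # first R
    assert out["hydrophobicity.g1.p100"] == pytest.approx(4 / 4)  # last R
    assert out["hydrophobicity.g3.p50"] == 0.0                    # group absent


def test_ctriad_homopolymer_peak_and_range():
    out = encode_ctriad("AAAA")
    assert out.shape == (343,)
    assert out.max() == 1.0 and out.min() >= 0.0
    # A is class 1 -> triad (1,1,1) is the unique maximum
    assert np.argmax(out) == 0
    assert encode_ctriad("AC").sum() == 0.0  # too short


# ---------------------------------------------------------------------------
# DDE / DDR
# ---------------------------------------------------------------------------

def test_dde_dipeptide_aa_matches_direct_arithmetic():
    tm = (4 / 61) ** 2
    tv = tm * (1 - tm) / (2 - 1)
    expected = (1 - tm) / math.sqrt(tv)
    out = dict(zip((a + b for a in AA_LIST for b in AA_LIST), encode_dde("AA")))
    assert out["AA"] == pytest.approx(expected)
    # absent dipeptide with positive expectation scores negative
    assert out["CC"] < 0
    assert encode_dde("AA").shape == (400,)


def test_dde_single_residue_errors():
    with pytest.raises(ValueError):
        encode_dde("A")


def test_ddr_gap_statistics():
    out = dict(zip(AA_LIST, encode_ddr("ACA")))
    assert out["A"] == pytest.approx(2 / 3)  # positions 0,2 -> gap 2, L=3
    assert out["C"] == 0.0                   # singleton -> sentinel
    assert out["W"] == 0.0                   # absent -> sentinel
    homo = dict(zip(AA_LIST, encode_ddr("AAAAA")))
    assert homo["A"] == pytest.approx(1 / 5)  # all gaps 1, normalized by L


@given(peptides)
def test_ddr_matches_position_enumeration(seq):
    out = dict(zip(AA_LIST, encode_ddr(seq)))
    for aa in set(seq):
        pos = [i for i, c in enumerate(seq) if c == aa]
        if len(pos) >= 2:
            gaps = [b - a for a, b in zip(pos, pos[1:])]
            assert out[aa] == pytest.approx(sum(gaps) / len(gaps) / len(seq))


# ---------------------------------------------------------------------------
# scale autocorrelation
# ---------------------------------------------------------------------------

def test_scale_descriptor_homopolymer_matches_hand_oracle():
    # On a homopolymer every product equals the squared standardized value.
    table = scales.Z3
    std_a = scales.standardized(table)["A"]
    out = encode_scale_descriptor("AAAAAA", table, nlag=4)
    expected = np.array([v * v for v in std_a for _ in range(4)])
    assert np.allclose(out, expected)


def test_scale_descriptor_short_sequence_zero_fills_long_lags():
    out = encode_scale_descriptor("ACD", scales.KYTE_DOOLITTLE, nlag=5)
    assert out.shape == (5,)
    assert (out[2:] == 0).all()  # lags 3..5 exceed the 3-mer


def test_scale_descriptor_mean_prepends_raw_average():
    out = encode_scale_descriptor("AC", scales.KYTE_DOOLITTLE, nlag=2,
                                  include_mean=True)
    kd = scales.KYTE_DOOLITTLE
    assert out[0] == pytest.approx((kd["A"] + kd["C"]) / 2)


# ---------------------------------------------------------------------------
# registry envelope
# ---------------------------------------------------------------------------

def test_default_registry_envelope():
    reg = default_registry()
    assert len(reg) == 58
    assert reg.total_size == 4335
    sizes = {sp.name: sp.size for sp in reg}
    assert sizes["CKSAAGP"] == 150
    assert sizes["Z5"] == 75
    assert sizes["Cougar"] == 30
    assert sizes["Ez"] == 30
    assert sizes["Z3"] == 30
    assert sizes["CTDC"] == 39
    assert sizes["ABHPRK"] == 105
    assert sizes["AAC"] == 20 and sizes["DPC"] == 400
    assert sizes["CTriad"] == 343 and sizes["DDE"] == 400
    assert sizes["CTDT"] == 39 and sizes["CTDD"] == 195


def test_registry_feature_names_unique_and_sized():
    reg = default_registry()
    names = reg.feature_names
    assert len(names) == len(set(names)) == 4335


def test_registry_subset_and_column_count(tiny_dataset):
    reg = default_registry().subset(["AAC", "DPC"])
    m = encode_all(tiny_dataset, reg)
    assert m.shape == (6, 420)
    assert m.columns[0] == "AAC.A"


def test_encode_all_deterministic_and_row_equivariant(tiny_dataset):
    reg = default_registry().subset(["AAC", "CTDC", "Z3", "SER"])
    m1 = encode_all(tiny_dataset, reg)
    m2 = encode_all(tiny_dataset, reg)
    assert m1.equals(m2)
    perm = [3, 0, 5, 1, 4, 2]
    shuffled = tiny_dataset.subset(perm)
    m3 = encode_all(shuffled, reg)
    assert np.allclose(m3.to_numpy(), m1.iloc[perm].to_numpy())


def test_encode_all_full_registry_no_missing(tiny_dataset):
    m = encode_all(tiny_dataset, default_registry())
    assert m.shape == (6, 4335)
    assert not m.isna().any().any()
    assert m.attrs["registry_hash"]


def test_registry_manifest_round_trip(tmp_path):
    reg = default_registry()
    path = tmp_path / "manifest.tsv"
    reg.write_manifest(path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("# registry hash")
    assert len(lines) == 60  # hash + header + 58 specs
    total = sum(int(l.split("\t")[1]) for l in lines[2:])
    assert total == 4335


def test_rejects_duplicate_spec_names():
    sp = DescriptorSpec("X", {}, ("X.a",), lambda s: np.zeros(1))
    with pytest.raises(ValueError):
        EncoderRegistry([sp, sp])


def test_length_encoder():
    assert encode_length("ACDE")[0] == 4.0


def test_frozen_rdkit_tables_match_recomputation():
    """The frozen free-amino-acid descriptors agree with a live RDKit run."""
    from rdkit import Chem
    from rdkit.Chem import Crippen, rdMolDescriptors

    smiles = {"G": "NCC(=O)O", "W": "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O",
              "K": "NCCCC[C@H](N)C(=O)O"}
    for aa, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        assert scales.RDKIT_TABLES["rd_logp"][aa] == pytest.approx(
            Crippen.MolLogP(mol), abs=1e-4)
        assert scales.RDKIT_TABLES["rd_tpsa"][aa] == pytest.approx(
            rdMolDescriptors.CalcTPSA(mol), abs=1e-4)
        assert scales.RDKIT_TABLES["rd_heavy_atoms"][aa] == mol.GetNumHeavyAtoms()
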