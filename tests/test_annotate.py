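import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmdkit.annotate import (
    classify_splice_site,
    classify_variant,
    codon_position,
    first_hidden_ptc,
    is_cpg_site,
    normalize_indel,
    ptc_codon,
    substitution_class,
)
from dmdkit.errors import ContractError, ReferenceMismatchError
from dmdkit.gene_model import STOP_CODONS, make_model
from dmdkit.hgvs import parse_hgvs

BASES = "ACGT"


def model_from_cds(cds, lengths=None):
    return make_model("MINI", lengths or (len(cds),), cds, domains=[("ABD", 1, 1)] if lengths is None else None)


# -- scalar helpers ----------------------------------------------------------


@pytest.mark.parametrize("pos,expected", [(1, 1), (2, 2), (6, 3), (6292, 1), (6293, 2)])
def test_codon_position(pos, expected):
    assert codon_position(pos) == expected


@pytest.mark.parametrize(
    "ref,alt,expected",
    [("C", "T", "transition"), ("G", "A", "transition"), ("A", "G", "transition"),
     ("C", "A", "transversion"), ("G", "T", "transversion"), ("A", "T", "transversion")],
)
def test_substitution_class(ref, alt, expected):
    assert substitution_class(ref, alt) == expected


def test_substitution_class_rejects_identity():
    with pytest.raises(ContractError):
        substitution_class("C", "C")


# -- consequence dispatch ----------------------------------------------------


def brute_force_consequence(ref_codon, cp, alt):
    """Independent statement of the substitution taxonomy via translation."""
    from Bio.Seq import Seq

    alt_codon = ref_codon[:cp] + alt + ref_codon[cp + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa != "*" and alt_aa == "*":
        return "nonsense"
    return "synonymous" if ref_aa == alt_aa else "missense"


def test_nonsense_iff_stop_gain_all_576_substitutions():
    """Nonsense <=> the alternate codon is a stop and the reference is not,
    checked over every single-base change of every codon (64 x 9 = 576)."""
    checked = 0
    for codon in map("".join, itertools.product(BASES, repeat=3)):
        if codon in STOP_CODONS:
            continue  # an internal stop is not a valid CDS
        # place the codon under test at codon 2
        model = model_from_cds("ATG" + codon + "GCT" + "TAA")
        for cp in range(3):
            for alt in BASES:
                if alt == codon[cp]:
                    continue
                pos = 4 + cp
                ann = classify_variant(model, f"c.{pos}{codon[cp]}>{alt}")
                assert ann.consequence == brute_force_consequence(codon, cp, alt)
                assert (ann.consequence == "nonsense") == (
                    ann.alt_codon in STOP_CODONS and ann.ref_codon not in STOP_CODONS
                )
                checked += 1
    assert checked == 61 * 9


def test_reference_mismatch_is_hard_error(toy_model):
    with pytest.raises(ReferenceMismatchError):
        classify_variant(toy_model, "c.4G>T")  # actual reference base is C


def test_classify_examples(toy_model):
    ann = classify_variant(toy_model, "c.4C>T")  # CAA -> TAA
    assert ann.consequence == "nonsense"
    assert ann.alt_codon == "TAA" and ann.ptc == "TAA"
    assert ann.host_exon == 1 and ann.domain == "ABD"
    assert classify_variant(toy_model, "c.-45A>G").consequence == "utr"
    assert classify_variant(toy_model, "c.91-2A>G").consequence == "splicing"
    fs = classify_variant(toy_model, "c.100delG")
    assert fs.consequence == "frameshift"


def test_ptc_codon_examples(toy_model):
    assert ptc_codon(toy_model, parse_hgvs("c.4C>T")) == "TAA"
    assert ptc_codon(toy_model, parse_hgvs("c.8G>A")) == "TAG"  # TGG -> TAG
    with pytest.raises(ContractError):
        ptc_codon(toy_model, parse_hgvs("c.5A>G"))


# -- CpG context -------------------------------------------------------------


def test_cpg_examples():
    model = model_from_cds("ATG" + "ACG" + "TCA" + "TAA")  # A[C]GT context at c.5
    assert is_cpg_site(model, parse_hgvs("c.5C>T")) is True
    assert is_cpg_site(model, parse_hgvs("c.6G>A")) is True  # AC[G]T
    assert is_cpg_site(model, parse_hgvs("c.8C>T")) is False  # T[C]A context


def test_cpg_requires_adjacent_g_or_c():
    model = model_from_cds("ATGCCATAA")
    assert is_cpg_site(model, parse_hgvs("c.5C>T")) is False  # C followed by A


@settings(derandomize=True, max_examples=200)
@given(st.integers(0, 3**8 - 1), st.integers(0, 7))
def test_cpg_strand_symmetry(ctx_seed, which):
    """CpG status is invariant under reverse-complementing the context and
    complementing the substituted base."""
    import numpy as np

    rng = np.random.default_rng(ctx_seed)
    comp = str.maketrans("ACGT", "TGCA")
    # build a random sense CDS of 8 codons
    from dmdkit.gene_model import STOP_CODONS as stops

    codons = []
    while len(codons) < 6:
        c = "".join(rng.choice(list("ACGT"), 3))
        if c not in stops:
            codons.append(c)
    cds = "ATG" + "".join(codons) + "TAA"
    pos = 4 + which  # inside the random middle
    ref = cds[pos - 1]
    model = model_from_cds(cds)
    alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
    fwd = is_cpg_site(model, parse_hgvs(f"c.{pos}{ref}>{alt}"))
    # reverse complement: the mirrored position in the flipped sequence
    rc = cds.translate(comp)[::-1]
    # make the flipped sequence a valid CDS frame-agnostically: check raw context
    p = len(cds) - pos + 1
    rref = rc[p - 1]
    manual = (rref == "C" and p < len(rc) and rc[p] == "G") or (
        rref == "G" and p > 1 and rc[p - 2] == "C"
    )
    assert fwd == manual


# -- hidden PTC --------------------------------------------------------------


def brute_hidden_ptc(cds, v):
    """Naive oracle: rebuild the mutant CDS and scan codons from the start."""
    from dmdkit.annotate import apply_indel

    mutant, first_changed = apply_indel(cds, v)
    k = (first_changed - 1) // 3  # 0-based first affected codon
    for i in range(k, len(mutant) // 3):
        codon = mutant[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            return codon, i + 1
    return None


def test_hidden_ptc_worked_examples():
    model = model_from_cds("ATGCTGATTTAA")
    hp = first_hidden_ptc(model, parse_hgvs("c.4delC"))
    assert (hp.stop, hp.codon_index, hp.codons_from_site) == ("TGA", 2, 1)
    assert first_hidden_ptc(model, parse_hgvs("c.6dupG")) is None
    with pytest.raises(ContractError):
        first_hidden_ptc(model, parse_hgvs("c.4_6del"))  # in-frame deletion


@settings(derandomize=True, max_examples=150)
@given(st.integers(0, 2**31 - 1))
def test_hidden_ptc_matches_translation_oracle(seed):
    import numpy as np

    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 40))
    codons = []
    while len(codons) < n:
        c = "".join(rng.choice(list("ACGT"), 3))
        if c not in STOP_CODONS:
            codons.append(c)
    cds = "ATG" + "".join(codons) + "TAA"
    model = model_from_cds(cds)
    L = len(cds)
    kind = rng.choice(["deletion", "duplication", "insertion"])
    if kind == "deletion":
        k = int(rng.choice([1, 2, 4]))
        s = int(rng.integers(1, L - k))
        seq = cds[s - 1 : s + k - 1]
        text = f"c.{s}del{seq}" if k == 1 else f"c.{s}_{s + k - 1}del{seq}"
    elif kind == "duplication":
        s = int(rng.integers(1, L))
        text = f"c.{s}dup{cds[s - 1]}"
    else:
        s = int(rng.integers(1, L - 1))
        ins = "".join(rng.choice(list("ACGT"), int(rng.choice([1, 2]))))
        text = f"c.{s}_{s + 1}ins{ins}"
    v = parse_hgvs(text)
    if v.net_length_change() % 3 == 0:
        return
    hp = first_hidden_ptc(model, v)
    oracle = brute_hidden_ptc(cds, v)
    if hp is None:
        assert oracle is None
    else:
        assert (hp.stop, hp.codon_index) == oracle


# -- splice-site classification ---------------------------------------------


@pytest.mark.parametrize(
    "text,side,cons",
    [
        ("c.186+2T>C", "donor", "core_1_2"),
        ("c.91-1G>T", "acceptor", "core_1_2"),
        ("c.90+4A>G", "donor", "near_3_5"),
        ("c.91-3_91-1delCAG", "acceptor", "spanning"),
        ("c.91-5_91-3del", "acceptor", "near_3_5"),
        ("c.90+7T>C", "donor", "other"),
    ],
)
def test_splice_site_classes(toy_model, text, side, cons):
    call = classify_splice_site(toy_model, parse_hgvs(text))
    assert (call.side, call.conservation) == (side, cons)


def test_splice_consensus_exons(toy_model):
    donor = classify_splice_site(toy_model, parse_hgvs("c.90+1G>A"))
    assert donor.consensus_exon == 1  # upstream exon of intron 1
    acceptor = classify_splice_site(toy_model, parse_hgvs("c.91-1G>A"))
    assert acceptor.consensus_exon == 2  # downstream exon
    spanning = classify_splice_site(toy_model, parse_hgvs("c.211-2_212del"))
    assert spanning.consensus_exon == 3  # the exonic endpoint's exon
    assert spanning.conservation == "spanning"


def test_splice_contract_requires_offset(toy_model):
    with pytest.raises(ContractError):
        classify_splice_site(toy_model, parse_hgvs("c.100C>T"))


def test_boundary_spanning_deletion_is_splicing(toy_model):
    ann = classify_variant(toy_model, "c.211-2_212del")
    assert ann.consequence == "splicing"


# -- indel normalization -----------------------------------------------------


def test_indel_normalization_left_and_right():
    # run of three T's at c.4-6: deletion placement is ambiguous
    model = model_from_cds("ATGTTTGCTTAA")
    v = parse_hgvs("c.5delT")
    left = normalize_indel(model, v)
    right = normalize_indel(model, v, three_prime=True)
    assert left.start.base == 4
    assert right.start.base == 6
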