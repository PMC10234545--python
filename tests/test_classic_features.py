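"""The eight classic coding-potential features."""

import json
from importlib import resources

import numpy as np
import pytest
from Bio.Seq import Seq

import lncwave as lw
from lncwave.classic_features import STOP_CODONS, peptide_net_charge


def exhaustive_orf_oracle(s):
    """Enumerate every ATG-initiated candidate; longest span, earliest start."""
    n = len(s)
    best = None
    for start in range(n - 2):
        if s[start:start + 3] != "ATG":
            continue
        end, has_stop = None, False
        i = start + 3
        while i + 3 <= n:
            if s[i:i + 3] in STOP_CODONS:
                end, has_stop = i + 3, True
                break
            i += 3
        if end is None:
            end = start + 3 * ((n - start) // 3)
        if best is None or (end - start, -start) > (best[1] - best[0], -best[0]):
            best = (start, end, has_stop)
    return best


def _seq(s):
    return lw.NucleotideSequence("t", s)


@pytest.mark.parametrize("s,expected", [
    ("ACGT", 50.0), ("AATT", 0.0), ("GGGCCC", 100.0),
])
def test_gc_content(s, expected):
    assert lw.gc_content(_seq(s)) == expected


@pytest.mark.parametrize("s,expected", [
    ("TAATAGTGA", 0.0),
    ("CCCCCCCCC", 0.0),
    ("TAATAA", np.sqrt(8.0 / 9.0)),
])
def test_stop_codon_std(s, expected):
    assert lw.stop_codon_std(_seq(s)) == pytest.approx(expected)


def test_stop_codon_counts_overlapping(rng):
    # substring counting sees overlapping occurrences: TAATAA has TAA at 0 and 3
    s = "TAATAA"
    assert lw.stop_codon_std(_seq(s)) == pytest.approx(np.sqrt(8 / 9))
    # per-frame mode counts the same triplets codon-aligned over all 3 frames
    assert lw.stop_codon_std(_seq(s), mode="per_frame_sum") == pytest.approx(
        np.sqrt(8 / 9))


def test_find_longest_orf_examples():
    orf = lw.find_longest_orf(_seq("ATGAAATAG"))
    assert (orf.start, orf.end, orf.has_start, orf.has_stop) == (0, 9, True, True)
    assert orf.peptide == "MK"
    assert lw.find_longest_orf(_seq("CCCCCC")) is None
    orf = lw.find_longest_orf(_seq("ATGAAA"))
    assert (orf.start, orf.end, orf.has_stop) == (0, 6, False)
    assert orf.peptide == "MK"


def test_find_longest_orf_matches_exhaustive_oracle(rng):
    for _ in range(500):
        n = int(rng.integers(10, 601))
        s = "".join(rng.choice(list("ACGT"), size=n))
        oracle = exhaustive_orf_oracle(s)
        orf = lw.find_longest_orf(_seq(s))
        if oracle is None:
            assert orf is None
        else:
            assert (orf.start, orf.end, orf.has_stop) == oracle


def test_orf_peptide_translates_back(rng):
    for _ in range(50):
        n = int(rng.integers(60, 400))
        s = "".join(rng.choice(list("ACGT"), size=n))
        orf = lw.find_longest_orf(_seq(s))
        if orf is None:
            continue
        coding_len = orf.span - (3 if orf.has_stop else 0)
        assert len(orf.peptide) == coding_len // 3
        # translating the ORF nucleotides reproduces the peptide
        assert str(Seq(_seq(s).residues[orf.start:orf.start + coding_len]
                       ).translate()) == orf.peptide


def test_orf_fullness_coding():
    complete = lw.find_longest_orf(_seq("ATGAAATAG"))
    partial = lw.find_longest_orf(_seq("ATGAAA"))
    assert lw.orf_fullness(complete) == 1.0
    assert lw.orf_fullness(partial) == 0.5
    assert lw.orf_fullness(None) == 0.0


def test_cds_percent():
    seq = _seq("ATGAAATAG" + "C" * 81)
    orf = lw.find_longest_orf(seq)
    assert lw.cds_percent(seq, orf) == pytest.approx(10.0)
    full = _seq("ATGAAATAG")
    assert lw.cds_percent(full, lw.find_longest_orf(full)) == 100.0
    assert lw.cds_percent(seq, None) == 0.0


def test_cds_score_surrogate():
    assert lw.cds_score(_seq("CCCCCC"), None) == 0.0
    # complete 300-bp ORF, no Kozak context
    s = "ATG" + "AAA" * 98 + "TAG"
    seq = _seq(s)
    assert lw.cds_score(seq, lw.find_longest_orf(seq)) == 400.0
    # Kozak bonus: R at -3 and G at +4
    s2 = "TTTACC" + "ATGG" + "AA" + "AAA" * 96 + "TAG"
    seq2 = _seq(s2)
    orf2 = lw.find_longest_orf(seq2)
    assert lw.cds_score(seq2, orf2) == orf2.span + 100 + 25


def test_cds_score_monotone_in_orf_length(rng):
    scores = []
    for n_codons in [10, 20, 40, 80, 160]:
        s = "ATG" + "GCT" * n_codons + "TAA"
        seq = _seq(s)
        scores.append(lw.cds_score(seq, lw.find_longest_orf(seq)))
    assert all(b > a for a, b in zip(scores, scores[1:]))


# ---------------------------------------------------------------------------
# Isoelectric point
# ---------------------------------------------------------------------------

def grid_search_pi(peptide, dph=1e-4):
    """Independent fine-grid sign-change search."""
    grid = np.arange(0.0, 14.0, dph)
    charges = np.array([peptide_net_charge(peptide, p) for p in grid])
    idx = np.flatnonzero(np.diff(np.sign(charges)))
    return grid[idx[0]] if len(idx) else float("nan")


def test_pi_zero_charge_at_returned_ph():
    for pep in ["GG", "MKKR", "DDEE", "ACDEFGHIKLMNPQRSTVWY"]:
        ph = lw.isoelectric_point(pep)
        assert abs(peptide_net_charge(pep, ph)) < 1e-2


def test_pi_acid_base_ordering():
    assert lw.isoelectric_point("DDDD") < lw.isoelectric_point("GGGG") \
        < lw.isoelectric_point("KKKK")


def test_pi_matches_grid_oracle():
    for pep in ["GG", "MKWLV", "DEKRH"]:
        assert lw.isoelectric_point(pep) == pytest.approx(
            grid_search_pi(pep), abs=1e-2)


def test_pi_sentinel_and_validation():
    assert lw.isoelectric_point("") == 0.0
    with pytest.raises(lw.SequenceValidationError):
        lw.isoelectric_point("GGX")


def test_pi_loosely_agrees_with_biopython():
    # different pKa conventions, so only a coarse cross-check
    from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
    for pep in ["MKWLVDE", "GGGKKDD", "ACDEFGHIKLMNPQRSTVWY"]:
        assert abs(lw.isoelectric_point(pep) - IsoelectricPoint(pep).pi()) < 1.0


# ---------------------------------------------------------------------------
# Fickett
# ---------------------------------------------------------------------------

def fickett_oracle(s):
    """Literal re-implementation straight from the shipped JSON tables."""
    tables = json.loads(resources.files("lncwave.data")
                        .joinpath("fickett_tables.json").read_text())

    def lookup(value, edges, probs):
        for e, p in zip(edges, probs):
            if value >= e:
                return p
        return probs[-1]

    total = 0.0
    for base in "ACGT":
        counts = [sum(1 for i in range(off, len(s), 3) if s[i] == base)
                  for off in range(3)]
        pos_val = max(counts) / (min(counts) + 1)
        cont_val = sum(counts) / len(s)
        total += tables["position_weight"][base] * lookup(
            pos_val, tables["position_edges"], tables["position_prob"][base])
        total += tables["content_weight"][base] * lookup(
            cont_val, tables["content_edges"], tables["content_prob"][base])
    return total


def test_fickett_matches_oracle(rng):
    for _ in range(50):
        s = "".join(rng.choice(list("ACGT"), size=int(rng.integers(3, 400))))
        assert lw.fickett_score(_seq(s)) == pytest.approx(fickett_oracle(s))


def test_fickett_periodic_beats_shuffle(rng):
    periodic = "ACG" * 60
    shuffled = "".join(rng.permutation(list(periodic)))
    assert lw.fickett_score(_seq(periodic)) > lw.fickett_score(_seq(shuffled))


def test_fickett_bounded_by_table_extremes(rng):
    tables = json.loads(resources.files("lncwave.data")
                        .joinpath("fickett_tables.json").read_text())
    lo = sum(min(tables["position_prob"][b]) * tables["position_weight"][b]
             + min(tables["content_prob"][b]) * tables["content_weight"][b]
             for b in "ACGT")
    hi = sum(max(tables["position_prob"][b]) * tables["position_weight"][b]
             + max(tables["content_prob"][b]) * tables["content_weight"][b]
             for b in "ACGT")
    for _ in range(30):
        s = "".join(rng.choice(list("ACGT"), size=int(rng.integers(3, 300))))
        assert lo <= lw.fickett_score(_seq(s)) <= hi


def test_fickett_needs_three_bases():
    with pytest.raises(lw.SequenceValidationError):
        lw.fickett_score(_seq("AC"))


def test_all_features_finite_with_sentinels():
    feats = lw.classic_features(_seq("A" * 300))
    vals = feats.as_dict()
    assert all(np.isfinite(v) for v in vals.values())
    assert vals["Orf_fullness"] == 0.0 and vals["CDS_Score"] == 0.0
    assert vals["PI"] == 0.0 and vals["CDS_percent"] == 0.0
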