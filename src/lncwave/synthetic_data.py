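"""Seeded generator of two separable transcript classes.

The coding-like class ("pcRNA") plants a long, codon-biased ORF — random
5'UTR, an in-frame stop guard, ATG, biased sense codons, a stop codon, random
3'UTR — covering a configurable fraction of the transcript. The
noncoding-like class ("lncRNA") is i.i.d. base sampling at the same expected
GC, with stop codons seeded into every frame at least every 90 bp so no long
ORF survives. Matching the GC means forces classifiers to rely on ORF and
wavelet structure rather than composition.

Everything is deterministic per seed; generators draw from independent
seeded streams so each class's FASTA is byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_io import NucleotideSequence

STOPS = ("TAA", "TAG", "TGA")
BASES = np.array(list("ACGT"))

#: Stop codons are planted at least this often (bp) in every frame of the
#: noncoding class, capping chance ORFs near the 30-codon floor.
STOP_SEED_INTERVAL = 90

#: Skewed sense-codon usage (relative weights, human-like preferences).
CODON_WEIGHTS = {
    "TTT": 17, "TTC": 20, "TTA": 7, "TTG": 13, "CTT": 13, "CTC": 20,
    "CTA": 7, "CTG": 40, "ATT": 16, "ATC": 21, "ATA": 7, "ATG": 22,
    "GTT": 11, "GTC": 15, "GTA": 7, "GTG": 28, "TCT": 15, "TCC": 18,
    "TCA": 12, "TCG": 4, "CCT": 17, "CCC": 20, "CCA": 17, "CCG": 7,
    "ACT": 13, "ACC": 19, "ACA": 15, "ACG": 6, "GCT": 18, "GCC": 28,
    "GCA": 16, "GCG": 7, "TAT": 12, "TAC": 15, "CAT": 11, "CAC": 15,
    "CAA": 12, "CAG": 34, "AAT": 17, "AAC": 19, "AAA": 24, "AAG": 32,
    "GAT": 22, "GAC": 25, "GAA": 29, "GAG": 40, "TGT": 11, "TGC": 13,
    "TGG": 13, "CGT": 5, "CGC": 10, "CGA": 6, "CGG": 11, "AGT": 12,
    "AGC": 19, "AGA": 12, "AGG": 12, "GGT": 11, "GGC": 22, "GGA": 17,
    "GGG": 16,
}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic two-class dataset."""

    n_per_class: int = 500
    length_range: tuple[int, int] = (250, 3000)
    gc_target: float = 0.5
    orf_fraction_coding: float = 0.6
    codon_bias_strength: float = 0.75
    seed: int = 7

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 206 or hi < lo:
            raise ValueError("length_range minimum must be >= 206 bp")
        for name in ("gc_target", "orf_fraction_coding", "codon_bias_strength"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")


def _codon_distribution(strength: float) -> tuple[list[str], np.ndarray]:
    codons = sorted(CODON_WEIGHTS)
    w = np.array([CODON_WEIGHTS[c] for c in codons], dtype=float)
    biased = w / w.sum()
    uniform = np.full(len(codons), 1.0 / len(codons))
    p = strength * biased + (1.0 - strength) * uniform
    return codons, p / p.sum()


def _gc_of_distribution(codons: list[str], p: np.ndarray) -> float:
    gc = np.array([(c.count("G") + c.count("C")) / 3.0 for c in codons])
    return float((p * gc).sum())


def _iid_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p)


def expected_coding_gc(config: SynthConfig) -> float:
    """Analytic mean GC of the coding-like class, used to match the classes."""
    codons, p = _codon_distribution(config.codon_bias_strength)
    gc_orf = _gc_of_distribution(codons, p)
    f = config.orf_fraction_coding
    return f * gc_orf + (1.0 - f) * config.gc_target


def generate_coding_like(config: SynthConfig) -> list[NucleotideSequence]:
    """Transcripts with a planted codon-biased ORF (label pcRNA)."""
    rng = np.random.default_rng([config.seed, 0])
    codons, p = _codon_distribution(config.codon_bias_strength)
    lo, hi = config.length_range
    out = []
    for i in range(config.n_per_class):
        length = int(rng.integers(lo, hi + 1))
        orf_nt = 3 * int(config.orf_fraction_coding * length // 3)
        orf_nt = max(orf_nt, 9)
        if orf_nt + 6 > length:
            raise ValueError(
                f"length {length} cannot hold a {orf_nt}-bp ORF plus UTRs"
            )
        utr5 = (length - orf_nt) // 2
        utr3 = length - orf_nt - utr5
        five = _iid_bases(rng, utr5, config.gc_target)
        # in-frame stop guard just upstream of the ATG, so upstream chance
        # ATGs cannot extend the planted ORF
        if utr5 >= 3:
            five[utr5 - 3:utr5] = list(STOPS[rng.integers(3)])
        n_mid = orf_nt // 3 - 2
        mid = rng.choice(codons, size=n_mid, p=p) if n_mid > 0 else []
        stop = STOPS[rng.integers(3)]
        three = _iid_bases(rng, utr3, config.gc_target)
        residues = "".join(five) + "ATG" + "".join(mid) + stop + "".join(three)
        out.append(NucleotideSequence(f"pc_{i:05d}", residues, label="pcRNA"))
    return out


def generate_noncoding_like(config: SynthConfig) -> list[NucleotideSequence]:
    """GC-matched i.i.d. transcripts with ORF-suppressing stop seeding (lncRNA)."""
    rng = np.random.default_rng([config.seed, 1])
    lo, hi = config.length_range
    # compensate the AT-rich planted stops so mean GC matches the coding class
    gc_target_eff = expected_coding_gc(config)
    frac_replaced = 3 * 3.0 / STOP_SEED_INTERVAL  # 3 frames x 3 bases / interval
    gc_stops = 2.0 / 9.0  # mean GC of a uniform random stop codon
    gc_sample = (gc_target_eff - frac_replaced * gc_stops) / (1.0 - frac_replaced)
    gc_sample = float(np.clip(gc_sample, 0.05, 0.95))
    out = []
    for i in range(config.n_per_class):
        length = int(rng.integers(lo, hi + 1))
        bases = _iid_bases(rng, length, gc_sample)
        for frame in range(3):
            for block in range(frame, length - 2, STOP_SEED_INTERVAL):
                slots = (min(length, block + STOP_SEED_INTERVAL) - block - 2) // 3
                if slots <= 0:
                    continue
                pos = block + 3 * int(rng.integers(slots))
                bases[pos:pos + 3] = list(STOPS[rng.integers(3)])
        out.append(NucleotideSequence(f"lnc_{i:05d}", "".join(bases),
                                      label="lncRNA"))
    return out


def generate_dataset(config: SynthConfig) -> list[NucleotideSequence]:
    """Both classes, noncoding (positives) first, deterministic per seed."""
    return generate_noncoding_like(config) + generate_coding_like(config)
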