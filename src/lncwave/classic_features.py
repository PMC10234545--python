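"""The eight classic coding-potential features.

Covers basic composition (length, GC%, stop-codon count dispersion), ORF
structure (integrity, a CDS score, CDS percentage), the isoelectric point of
the longest-ORF peptide, and the Fickett TESTCODE statistic. The CDS score is
a documented in-package surrogate for txCdsPredict's output (span plus
start/stop/Kozak bonuses); an adapter that shells out to an installed
txCdsPredict binary is available for users who have it.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from .sequence_io import NucleotideSequence, SequenceValidationError

CLASSIC_FEATURE_NAMES = (
    "seq_len", "GC_content", "Stop_std", "Orf_fullness",
    "CDS_Score", "CDS_percent", "PI", "Fickett_Score",
)

STOP_CODONS = ("TAA", "TAG", "TGA")

# surrogate CDS-score weights
_W_START = 50.0
_W_STOP = 50.0
_W_KOZAK = 25.0
_W_INTERNAL_STOP = -10.0


@dataclass
class OrfRecord:
    """Longest forward-frame ORF: ATG-initiated, stop-terminated when possible."""

    start: int   # 0-based inclusive
    end: int     # 0-based exclusive
    frame: int
    has_start: bool
    has_stop: bool
    peptide: str

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class ClassicFeatures:
    seq_len: int
    gc_content: float
    stop_std: float
    orf_fullness: float
    cds_score: float
    cds_percent: float
    pi: float
    fickett: float

    def as_dict(self) -> dict[str, float]:
        return dict(zip(CLASSIC_FEATURE_NAMES, (
            float(self.seq_len), self.gc_content, self.stop_std,
            self.orf_fullness, self.cds_score, self.cds_percent,
            self.pi, self.fickett,
        )))


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def gc_content(seq: NucleotideSequence) -> float:
    """GC percentage of the transcript."""
    s = seq.residues
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def _count_overlapping(text: str, pattern: str) -> int:
    count = start = 0
    while True:
        idx = text.find(pattern, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def stop_codon_std(seq: NucleotideSequence, mode: str = "substring") -> float:
    """Population standard deviation of TAA/TAG/TGA counts.

    ``substring`` counts occurrences at every offset; ``per_frame_sum`` counts
    codon-aligned occurrences summed over the three frames (equivalent for
    these patterns except at the last two positions, kept for completeness).
    """
    s = seq.residues
    if mode == "substring":
        counts = [_count_overlapping(s, c) for c in STOP_CODONS]
    elif mode == "per_frame_sum":
        counts = []
        for c in STOP_CODONS:
            total = 0
            for f in range(3):
                codons = [s[i:i + 3] for i in range(f, len(s) - 2, 3)]
                total += codons.count(c)
            counts.append(total)
    else:
        raise ValueError(f"unknown stop_count_mode {mode!r}")
    return float(np.std(counts))


# ---------------------------------------------------------------------------
# ORF features
# ---------------------------------------------------------------------------

def find_longest_orf(seq: NucleotideSequence) -> Optional[OrfRecord]:
    """Longest ORF over the three forward frames.

    Candidates are ATG..stop runs (earliest unclosed ATG to its first in-frame
    stop) plus a terminal ATG-initiated run without a stop codon. Ties in span
    go to the smaller start, then lower frame. Returns None when no ATG exists.
    """
    s = seq.residues
    n = len(s)
    best: Optional[OrfRecord] = None

    def better(cand: OrfRecord) -> bool:
        if best is None:
            return True
        return (cand.span, -cand.start, -cand.frame) > (best.span, -best.start, -best.frame)

    for frame in range(3):
        open_start = None
        i = frame
        while i + 3 <= n:
            codon = s[i:i + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = i
            elif codon in STOP_CODONS:
                cand = _make_orf(s, open_start, i + 3, frame, has_stop=True)
                if better(cand):
                    best = cand
                open_start = None
            i += 3
        if open_start is not None:
            end = open_start + 3 * ((n - open_start) // 3)
            cand = _make_orf(s, open_start, end, frame, has_stop=False)
            if better(cand):
                best = cand
    return best


def _make_orf(s: str, start: int, end: int, frame: int, has_stop: bool) -> OrfRecord:
    coding = s[start:end - 3] if has_stop else s[start:end]
    peptide = str(Seq(coding).translate()) if coding else ""
    return OrfRecord(start, end, frame, has_start=True, has_stop=has_stop,
                     peptide=peptide)


def orf_fullness(orf: Optional[OrfRecord]) -> float:
    """1.0 both ends present, 0.5 exactly one, 0.0 no ORF."""
    if orf is None:
        return 0.0
    return 0.5 * (int(orf.has_start) + int(orf.has_stop))


def cds_percent(seq: NucleotideSequence, orf: Optional[OrfRecord]) -> float:
    if orf is None:
        return 0.0
    return 100.0 * orf.span / seq.length


def _kozak_bonus(seq: NucleotideSequence, orf: OrfRecord) -> float:
    """+25 when the context matches R at -3 and G at +4 around the ATG."""
    s, a = seq.residues, orf.start
    if a >= 3 and a + 3 < len(s) and s[a - 3] in "AG" and s[a + 3] == "G":
        return _W_KOZAK
    return 0.0


def cds_score(seq: NucleotideSequence, orf: Optional[OrfRecord],
              mode: str = "surrogate") -> float:
    """CDS plausibility score.

    Default surrogate: ORF span + 50 per present start/stop + 25 Kozak bonus
    - 10 per in-frame internal stop (zero by construction of the ORF scan).
    ``mode='txcdspredict'`` shells out to an installed txCdsPredict binary.
    """
    if mode == "txcdspredict":
        return _txcdspredict_scores([seq])[seq.seq_id]
    if mode != "surrogate":
        raise ValueError(f"unknown cds mode {mode!r}")
    if orf is None:
        return 0.0
    score = float(orf.span)
    score += _W_START * orf.has_start + _W_STOP * orf.has_stop
    score += _kozak_bonus(seq, orf)
    internal_stops = orf.peptide.count("*")
    score += _W_INTERNAL_STOP * internal_stops
    return score


def _txcdspredict_scores(seqs: list[NucleotideSequence]) -> dict[str, float]:
    """Adapter: run an installed txCdsPredict and parse its score column."""
    exe = shutil.which("txCdsPredict")
    if exe is None:
        raise EnvironmentError(
            "cds mode 'txcdspredict' requires the txCdsPredict binary on PATH"
        )
    from .sequence_io import write_fasta
    with tempfile.TemporaryDirectory() as tmp:
        fa = Path(tmp) / "in.fa"
        out = Path(tmp) / "out.cds"
        write_fasta(seqs, fa)
        subprocess.run([exe, str(fa), str(out)], check=True)
        scores = {s.seq_id: 0.0 for s in seqs}
        for line in out.read_text().splitlines():
            parts = line.split("\t")
            if len(parts) >= 5:
                scores[parts[0]] = max(scores.get(parts[0], 0.0), float(parts[4]))
        return scores


# ---------------------------------------------------------------------------
# Isoelectric point
# ---------------------------------------------------------------------------

def _load_pka() -> dict:
    text = resources.files("lncwave.data").joinpath("pka_emboss.json").read_text()
    return json.loads(text)


_PKA = _load_pka()
_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


def peptide_net_charge(peptide: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge of a peptide at a given pH."""
    pos = [(_PKA["n_terminus"], 1)]
    neg = [(_PKA["c_terminus"], 1)]
    for aa, pka in _PKA["positive"].items():
        k = peptide.count(aa)
        if k:
            pos.append((pka, k))
    for aa, pka in _PKA["negative"].items():
        k = peptide.count(aa)
        if k:
            neg.append((pka, k))
    charge = sum(n / (1.0 + 10.0 ** (ph - pka)) for pka, n in pos)
    charge -= sum(n / (1.0 + 10.0 ** (pka - ph)) for pka, n in neg)
    return charge


def isoelectric_point(peptide: str, tol: float = 1e-3) -> float:
    """pH at which the peptide's net charge crosses zero (bisection on [0, 14]).

    An empty peptide returns the 0.0 sentinel.
    """
    if not peptide:
        return 0.0
    bad = set(peptide) - _AA20
    if bad:
        raise SequenceValidationError(
            f"peptide contains non-standard residues {sorted(bad)}"
        )
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if peptide_net_charge(peptide, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Fickett TESTCODE
# ---------------------------------------------------------------------------

def _load_fickett() -> dict:
    text = resources.files("lncwave.data").joinpath("fickett_tables.json").read_text()
    return json.loads(text)


_FICKETT = _load_fickett()


def _lookup(value: float, edges: list[float], probs: list[float]) -> float:
    for edge, prob in zip(edges, probs):
        if value >= edge:
            return prob
    return probs[-1]


def fickett_score(seq: NucleotideSequence) -> float:
    """Fickett TESTCODE statistic.

    For each base, the position value is the maximum of its counts at the
    three codon positions divided by (minimum + 1), and the composition value
    is its overall frequency; each of the eight values is binned through the
    published lookup tables and the probabilities combined with the published
    weights.
    """
    s = seq.residues
    if len(s) < 3:
        raise SequenceValidationError("Fickett score needs length >= 3")
    score = 0.0
    for base in "ACGT":
        counts = [s[off::3].count(base) for off in range(3)]
        position_value = max(counts) / (min(counts) + 1.0)
        content_value = sum(counts) / len(s)
        score += _FICKETT["position_weight"][base] * _lookup(
            position_value, _FICKETT["position_edges"],
            _FICKETT["position_prob"][base])
        score += _FICKETT["content_weight"][base] * _lookup(
            content_value, _FICKETT["content_edges"],
            _FICKETT["content_prob"][base])
    return score


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

def classic_features(seq: NucleotideSequence, cds_mode: str = "surrogate",
                     stop_count_mode: str = "substring") -> ClassicFeatures:
    """All eight classic features for one transcript (sentinels when no ORF)."""
    orf = find_longest_orf(seq)
    peptide = orf.peptide.replace("*", "") if orf is not None else ""
    return ClassicFeatures(
        seq_len=seq.length,
        gc_content=gc_content(seq),
        stop_std=stop_codon_std(seq, mode=stop_count_mode),
        orf_fullness=orf_fullness(orf),
        cds_score=cds_score(seq, orf, mode=cds_mode),
        cds_percent=cds_percent(seq, orf),
        pi=isoelectric_point(peptide),
        fickett=fickett_score(seq),
    )
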