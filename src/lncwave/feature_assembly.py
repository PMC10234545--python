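"""Assembly of the 15-column feature table and the Pearson correlation screen."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .sequence_io import NucleotideSequence
from .signal_transform import (
    EncodingTable, MorseParams, cwt, encode, get_encoding_table,
)
from .scws_features import (
    WAVELET_FEATURE_NAMES, scws, segments_above_mean, wavelet_features,
)
from .classic_features import CLASSIC_FEATURE_NAMES, classic_features

logger = logging.getLogger(__name__)

#: Canonical column order of the full feature table.
CANONICAL_FEATURES = tuple(CLASSIC_FEATURE_NAMES) + tuple(WAVELET_FEATURE_NAMES)


@dataclass
class PipelineConfig:
    """Everything that determines a feature table, recorded for reproducibility."""

    encoding_table: str = "pk_default"
    wavelet: MorseParams = field(default_factory=MorseParams)
    third_rule: str = "top_rank"
    variance_mode: str = "population"
    stop_count_mode: str = "substring"
    cds_mode: str = "surrogate"
    correlation_threshold: float = 0.8

    def snapshot(self) -> dict:
        d = asdict(self)
        d["wavelet"] = asdict(self.wavelet)
        return d


def features_for_sequence(seq: NucleotideSequence,
                          config: PipelineConfig) -> dict[str, float]:
    """One transcript's 15 named features under a single configuration."""
    table = get_encoding_table(config.encoding_table)
    row = classic_features(seq, cds_mode=config.cds_mode,
                           stop_count_mode=config.stop_count_mode).as_dict()
    scal = cwt(encode(seq, table), config.wavelet)
    profile = scws(scal)
    segs = segments_above_mean(profile)
    row.update(wavelet_features(segs, third_rule=config.third_rule,
                                variance_mode=config.variance_mode).as_dict())
    return row


def assemble(seqs: list[NucleotideSequence],
             config: PipelineConfig | None = None) -> pd.DataFrame:
    """Feature table: one row per transcript, columns in canonical order.

    Rows whose feature extraction fails are skipped with a logged reason; the
    number skipped is reported. A ``label`` column is appended when any input
    carries a label.
    """
    config = config or PipelineConfig()
    rows, index, labels = [], [], []
    n_failed = 0
    for seq in seqs:
        try:
            rows.append(features_for_sequence(seq, config))
        except Exception as exc:  # noqa: BLE001 - per-row isolation is the contract
            n_failed += 1
            logger.warning("skipping %s: %s", seq.seq_id, exc)
            continue
        index.append(seq.seq_id)
        labels.append(seq.label)
    if n_failed:
        logger.warning("feature extraction skipped %d/%d transcripts",
                       n_failed, len(seqs))
    df = pd.DataFrame(rows, index=pd.Index(index, name="seq_id"),
                      columns=list(CANONICAL_FEATURES))
    if any(lab is not None for lab in labels):
        df["label"] = labels
    if not np.isfinite(df[list(CANONICAL_FEATURES)].to_numpy()).all():
        raise ValueError("feature table contains non-finite values")
    return df


def correlation_filter(table: pd.DataFrame,
                       threshold: float = 0.8) -> list[str]:
    """Greedy Pearson redundancy screen; returns surviving feature names.

    Pairs with |r| above the threshold are scanned in canonical column order
    and the later-ordered member of each offending pair is dropped.
    Zero-variance columns have undefined correlations; those pairs are treated
    as r = 0 (and logged), so constant columns are never dropped for
    redundancy.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    cols = [c for c in table.columns if c != "label"]
    if len(table) < 2:
        raise ValueError("correlation filter needs at least 2 rows")
    X = table[cols].to_numpy(dtype=float)
    std = X.std(axis=0)
    degenerate = std == 0
    if degenerate.any():
        logger.warning("zero-variance columns treated as uncorrelated: %s",
                       [c for c, d in zip(cols, degenerate) if d])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)

    dropped = np.zeros(len(cols), dtype=bool)
    for i in range(len(cols)):
        if dropped[i]:
            continue
        for j in range(i + 1, len(cols)):
            if not dropped[j] and abs(corr[i, j]) > threshold:
                dropped[j] = True
    return [c for c, d in zip(cols, dropped) if not d]


def write_features(table: pd.DataFrame, path) -> None:
    """TSV round-trip format: seq_id first, label (if any) last."""
    table.to_csv(path, sep="\t", index=True, float_format="%.10g")


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="seq_id")
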