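"""Numeric encoding of transcripts and the generalized Morse wavelet transform.

A transcript is mapped base-by-base to a real amplitude signal through a
four-entry encoding table, and the signal is analysed with the analytic
generalized Morse wavelet

    phi(beta, gamma, omega) = U(omega) * a_{beta,gamma} * omega**beta
                              * exp(-omega**gamma)

with the conventional (beta, gamma) = (20, 3). The transform is computed in
the frequency domain: the zero-meaned, padded signal's spectrum is multiplied
by the wavelet's frequency response at each layer's scale and inverted. Layer
j (1-based) is assigned scale s_j = j * omega_p / (2*pi), where
omega_p = (beta/gamma)**(1/gamma) is the wavelet's peak frequency, so a layer
index reads as an approximate footprint in bases. L1 scale normalization is
used (the time-domain wavelet is psi(t/s)/s), which keeps peak magnitudes
comparable across layers; a_{beta,gamma} is fixed so the frequency-domain
peak value is 2, the usual analytic-wavelet convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from .sequence_io import NucleotideSequence, SequenceValidationError


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EncodingTable:
    """Base -> amplitude map used to turn a transcript into a signal."""

    name: str
    mapping: dict[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = set("ACGT") - set(self.mapping)
        if missing:
            raise ValueError(f"encoding table {self.name!r} missing {sorted(missing)}")
        vals = [self.mapping[b] for b in "ACGT"]
        if not all(np.isfinite(vals)):
            raise ValueError(f"encoding table {self.name!r} has non-finite amplitudes")
        if len(set(vals)) < 2:
            raise ValueError(
                f"encoding table {self.name!r} maps every base to the same value"
            )


def _load_builtin_tables() -> dict[str, EncodingTable]:
    text = resources.files("lncwave.data").joinpath("encoding_tables.json").read_text()
    raw = json.loads(text)
    return {
        name: EncodingTable(name, entry["mapping"], entry.get("provenance", ""))
        for name, entry in raw.items()
    }


BUILTIN_ENCODING_TABLES = _load_builtin_tables()


def get_encoding_table(name: str = "pk_default") -> EncodingTable:
    try:
        return BUILTIN_ENCODING_TABLES[name]
    except KeyError:
        raise KeyError(
            f"unknown encoding table {name!r}; "
            f"available: {sorted(BUILTIN_ENCODING_TABLES)}"
        ) from None


@dataclass
class NumericSignal:
    values: np.ndarray
    source_id: str

    def __len__(self) -> int:
        return len(self.values)


def encode(seq: NucleotideSequence, table: EncodingTable) -> NumericSignal:
    """Look each residue up in the encoding table."""
    if seq.length == 0:
        raise SequenceValidationError("cannot encode an empty sequence")
    lut = np.zeros(256)
    for base, amp in table.mapping.items():
        lut[ord(base)] = amp
    codes = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
    return NumericSignal(lut[codes], seq.seq_id)


# ---------------------------------------------------------------------------
# Morse wavelet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorseParams:
    """Generalized Morse wavelet and layer-grid configuration."""

    beta: float = 20.0
    gamma: float = 3.0
    n_layers_total: int = 35
    n_layers_sum: int = 20
    padding: str = "reflect"  # reflect | zero | periodic

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.gamma <= 0:
            raise ValueError("beta and gamma must be positive")
        if not 1 <= self.n_layers_sum <= self.n_layers_total:
            raise ValueError("need 1 <= n_layers_sum <= n_layers_total")
        if self.padding not in ("reflect", "zero", "periodic"):
            raise ValueError(f"unknown padding {self.padding!r}")

    @property
    def peak_omega(self) -> float:
        """Frequency at which the wavelet magnitude peaks: (beta/gamma)**(1/gamma)."""
        return (self.beta / self.gamma) ** (1.0 / self.gamma)

    @property
    def norm_constant(self) -> float:
        """a_{beta,gamma} such that phi(peak_omega) = 2."""
        r = self.beta / self.gamma
        return 2.0 * np.exp(r * (1.0 + np.log(self.gamma / self.beta)))

    @property
    def layer_scales(self) -> np.ndarray:
        """Scale of each layer; layer j covers roughly a j-base footprint."""
        per_base = self.peak_omega / (2.0 * np.pi)
        return per_base * np.arange(1, self.n_layers_total + 1, dtype=float)


def morse_wavelet_hat(omega, params: MorseParams):
    """Frequency response phi(beta, gamma, omega); zero for omega <= 0."""
    scalar = np.isscalar(omega) or np.ndim(omega) == 0
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    out = np.zeros_like(omega)
    pos = omega > 0
    with np.errstate(under="ignore"):
        logphi = (
            np.log(params.norm_constant)
            + params.beta * np.log(omega[pos])
            - omega[pos] ** params.gamma
        )
        out[pos] = np.exp(logphi)
    if scalar:
        return float(out[0])
    return out


@dataclass
class Scalogram:
    """Complex wavelet coefficients, shape (n_layers_total, signal_length)."""

    coeffs: np.ndarray
    layer_scales: np.ndarray
    params: MorseParams
    source_id: str = ""

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.coeffs)


def wavelet_filter_bank(n_fft: int, params: MorseParams) -> np.ndarray:
    """Filter bank phi(s_j * omega_k), zeroed on negative frequencies.

    omega_k = 2*pi*k/n_fft for k = 0..n_fft-1; bins above n_fft//2 represent
    negative frequencies and get zero response (the wavelet is analytic).
    """
    k = np.arange(n_fft)
    omega = 2.0 * np.pi * k / n_fft
    bank = morse_wavelet_hat(
        params.layer_scales[:, None] * omega[None, :], params
    )
    bank[:, n_fft // 2 + 1:] = 0.0
    return bank


def _pad(x: np.ndarray, mode: str) -> tuple[np.ndarray, int]:
    """Pad to a power of two at least twice the length; returns (padded, left_pad)."""
    n = len(x)
    if mode == "periodic":
        return x, 0
    m = 1 << int(np.ceil(np.log2(2 * n)))
    left = (m - n) // 2
    right = m - n - left
    if mode == "zero":
        xp = np.pad(x, (left, right))
    else:  # reflect
        xp = np.pad(x, (left, right), mode="reflect")
    return xp, left


def cwt(signal: NumericSignal, params: MorseParams = MorseParams()) -> Scalogram:
    """Continuous Morse wavelet transform of a base-amplitude signal.

    The signal is zero-meaned, padded per ``params.padding``, transformed,
    multiplied by each layer's wavelet frequency response, inverted, and
    trimmed back to the input length.
    """
    x = np.asarray(signal.values, dtype=float)
    if len(x) < 2:
        raise SequenceValidationError("cwt needs a signal of length >= 2")
    x = x - x.mean()
    xp, left = _pad(x, params.padding)
    spectrum = np.fft.fft(xp)
    bank = wavelet_filter_bank(len(xp), params)
    coeffs = np.fft.ifft(spectrum[None, :] * bank, axis=1)
    coeffs = coeffs[:, left:left + len(x)]
    return Scalogram(coeffs, params.layer_scales, params, signal.source_id)
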