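"""Contact-map predictor contract, surrogate implementation, and registry.

A predictor maps a fixed-length nucleotide sequence to a log-scaled
observed/expected contact map over the central output span.  The trained
neural network is one such predictor and plugs in through this seam; the
package ships a deterministic motif-insulation surrogate so that every
downstream stage can run and be tested without model weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np

from .geometry import PredictorGeometry

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ContactMap:
    """Symmetric log-O/E contact map over fixed bins.

    ``values`` is the full symmetric ``n_bins x n_bins`` matrix;
    ``bin_mask`` flags valid bins; entries within ``diagonal_offset`` bands
    of the diagonal are excluded from every comparison.
    """

    geometry: PredictorGeometry
    values: np.ndarray
    bin_mask: np.ndarray
    diagonal_offset: int = 2

    def __post_init__(self) -> None:
        n = self.geometry.n_bins
        if self.values.shape != (n, n):
            raise ValueError(f"expected {(n, n)} matrix, got {self.values.shape}")
        if self.bin_mask.shape != (n,):
            raise ValueError("bin_mask must be per-bin")

    @property
    def n_bins(self) -> int:
        return self.geometry.n_bins

    def value(self, i: int, j: int) -> float:
        return float(self.values[i, j])

    def offdiag_selector(self) -> np.ndarray:
        """Boolean matrix marking entries outside the excluded diagonal bands."""
        n = self.n_bins
        idx = np.arange(n)
        return np.abs(idx[:, None] - idx[None, :]) >= self.diagonal_offset

    def copy(self) -> "ContactMap":
        return ContactMap(
            self.geometry, self.values.copy(), self.bin_mask.copy(), self.diagonal_offset
        )


class Predictor(Protocol):
    geometry: PredictorGeometry

    def __call__(self, sequence: str) -> ContactMap: ...


#: Fixed 19-mer used by the surrogate as its boundary element (CTCF-like
#: core consensus).  Frozen so derived expectations in tests are stable.
DEFAULT_BOUNDARY_MOTIF = "CCACCAGGGGGCGCTAGTG"


@dataclass(frozen=True)
class SurrogateParams:
    """Frozen parameters of the motif-insulation surrogate."""

    motif: str = DEFAULT_BOUNDARY_MOTIF
    sigma: float = 1.0  # insulation depth per boundary between two bins
    alpha: float = 0.25  # distance-decay exponent on log(|i-j|+1)

    def __post_init__(self) -> None:
        if not self.motif or set(self.motif) - set("ACGT"):
            raise ValueError("motif must be a nonempty ACGT string")


def _motif_hit_centers(sequence: str, motif: str) -> list[int]:
    """Centers of all motif occurrences on either strand (may overlap)."""
    centers = []
    half = len(motif) // 2
    for probe in (motif, reverse_complement(motif)):
        at = sequence.find(probe)
        while at != -1:
            centers.append(at + half)
            at = sequence.find(probe, at + 1)
    return sorted(set(centers))


@dataclass
class SurrogatePredictor:
    """Deterministic stand-in for a learned contact-map model.

    The map is a distance-decay baseline with block insulation at boundary
    motifs::

        value(i, j) = -alpha * log(|i - j| + 1) - sigma * B(i, j)

    where ``B(i, j)`` counts boundary motifs in bins strictly between ``i``
    and ``j``.  Motifs are detected on both strands, so the map of a
    reverse-complemented sequence is the anti-transpose of the original —
    the equivariance that makes augmentation averaging meaningful.
    """

    geometry: PredictorGeometry = field(default_factory=PredictorGeometry)
    params: SurrogateParams = field(default_factory=SurrogateParams)
    diagonal_offset: int = 2

    def __call__(self, sequence: str) -> ContactMap:
        g = self.geometry
        seq = _validate_sequence(sequence, g)
        n = g.n_bins
        idx = np.arange(n)
        sep = np.abs(idx[:, None] - idx[None, :])
        values = -self.params.alpha * np.log(sep + 1.0)

        motif_bins = []
        for center in _motif_hit_centers(seq, self.params.motif):
            b = (center - g.crop_bp) // g.bin_bp
            if 0 <= b < n:
                motif_bins.append(int(b))
        if motif_bins:
            # boundaries strictly between i < j: count motif bins m with i < m < j
            counts = np.zeros(n, dtype=np.int64)
            for b in motif_bins:
                counts[b] += 1
            cum = np.cumsum(counts)  # cum[k] = motifs in bins <= k
            lo = np.minimum(idx[:, None], idx[None, :])
            hi = np.maximum(idx[:, None], idx[None, :])
            between = np.where(hi > lo, cum[np.maximum(hi - 1, 0)] - cum[lo], 0)
            values = values - self.params.sigma * between

        return ContactMap(
            geometry=g,
            values=values,
            bin_mask=np.ones(n, dtype=bool),
            diagonal_offset=self.diagonal_offset,
        )


def _validate_sequence(sequence: str, geometry: PredictorGeometry) -> str:
    if len(sequence) != geometry.input_span_bp:
        raise ValueError(
            f"sequence length {len(sequence)} != expected {geometry.input_span_bp}"
        )
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    return seq


# --- registry -------------------------------------------------------------

_REGISTRY: dict[str, Callable[[PredictorGeometry], Predictor]] = {}


def register_predictor(name: str, factory: Callable[[PredictorGeometry], Predictor]) -> None:
    _REGISTRY[name] = factory


def get_predictor(name: str, geometry: PredictorGeometry | None = None) -> Predictor:
    if name not in _REGISTRY:
        raise KeyError(f"unknown predictor {name!r}; registered: {sorted(_REGISTRY)}")
    return _REGISTRY[name](geometry or PredictorGeometry())


register_predictor("surrogate", lambda g: SurrogatePredictor(geometry=g))
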