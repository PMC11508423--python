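"""Sliding-window amino-acid propensity profiles (alpha-helix, beta-sheet,
beta-turn, coil) with the linear weight variation model, and quantitative
profile comparison.

The per-residue propensity tables ship as a versioned JSON data file
(the Deleage-Roux conformational parameter set used by the ExPASy
ProtScale service) and are swappable. A profile value at center c is the
weighted mean of the scale values in the window around c; under the linear
weight variation model the weights fall linearly from 1.0 at the center to
``edge_weight_percent``/100 at both window edges (100% = a plain moving
average).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.stats import pearsonr

from .seqio import PROTEIN, SequenceRecord
from .pairalign import PairwiseAlignment

SCALE_NAMES = ("alpha_helix", "beta_sheet", "beta_turn", "coil")


@dataclass(frozen=True)
class PropensityScale:
    name: str
    values: dict

    def __post_init__(self) -> None:
        if len(self.values) != 20:
            raise ValueError("a propensity scale needs exactly 20 entries")
        if not all(np.isfinite(v) for v in self.values.values()):
            raise ValueError("scale values must be finite")

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.values.values())))

    def value(self, residue: str) -> float:
        """Scale value; unknown residues (X) use the scale mean."""
        return self.values.get(residue, self.mean)


@dataclass
class PropensityProfile:
    scale_name: str
    window: int
    edge_weight_percent: float
    positions: np.ndarray   # 1-based center residue positions
    values: np.ndarray

    def value_at(self, residue_position: int) -> float | None:
        """Profile value at a 1-based residue position, if it is a center."""
        i = residue_position - int(self.positions[0])
        if 0 <= i < len(self.values):
            return float(self.values[i])
        return None


def _load_tables() -> dict:
    text = (resources.files("ripscan") / "data" /
            "deleage_roux_scales.json").read_text()
    return json.loads(text)["scales"]


_TABLES = None


def available_scales() -> tuple[str, ...]:
    return SCALE_NAMES


def get_scale(name: str) -> PropensityScale:
    global _TABLES
    if _TABLES is None:
        _TABLES = _load_tables()
    if name not in _TABLES:
        raise KeyError(f"unknown scale {name!r}; available: {SCALE_NAMES}")
    return PropensityScale(name, dict(_TABLES[name]))


def window_weights(window: int, edge_weight_percent: float) -> np.ndarray:
    """Linear weight variation: edge_weight/100 at the edges, 1.0 at center."""
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    e = edge_weight_percent / 100.0
    half = window // 2
    if half == 0:
        return np.ones(1)
    ramp = e + (1.0 - e) * (1.0 - np.abs(np.arange(window) - half) / half)
    return ramp


def propensity_profile(protein: SequenceRecord, scale: PropensityScale | str,
                       window: int = 21,
                       edge_weight_percent: float = 100.0) -> PropensityProfile:
    """Sliding-window weighted propensity profile of a protein.

    The profile has length n - window + 1 with 1-based center positions
    (window+1)/2 .. n - (window-1)/2.
    """
    if protein.molecule != PROTEIN:
        raise ValueError("propensity_profile requires a protein record")
    if isinstance(scale, str):
        scale = get_scale(scale)
    n = len(protein.seq)
    if window > n:
        raise ValueError(f"sequence length {n} shorter than window {window}")
    weights = window_weights(window, edge_weight_percent)
    per_residue = np.array([scale.value(aa) for aa in protein.seq])
    # weighted moving average via correlation with the weight kernel
    values = np.correlate(per_residue, weights, mode="valid") / weights.sum()
    half = window // 2
    positions = np.arange(half + 1, n - half + 1)
    return PropensityProfile(scale.name, window, edge_weight_percent,
                             positions, values)


def profile_similarity(a: PropensityProfile, b: PropensityProfile,
                       mapping: PairwiseAlignment,
                       min_overlap: int = 10) -> float:
    """Pearson correlation of two profiles over alignment-matched centers.

    ``mapping`` aligns the two underlying proteins (query = a's protein,
    subject = b's protein). Columns where both rows carry a residue whose
    position is a valid profile center in both proteins contribute a pair.
    """
    if a.scale_name != b.scale_name or a.window != b.window:
        raise ValueError("profiles must share scale and window")
    xa, xb = [], []
    pos_a = pos_b = 0
    for qc, sc in zip(mapping.aligned_query, mapping.aligned_subject):
        if qc != "-":
            pos_a += 1
        if sc != "-":
            pos_b += 1
        if qc != "-" and sc != "-":
            va = a.value_at(pos_a)
            vb = b.value_at(pos_b)
            if va is not None and vb is not None:
                xa.append(va)
                xb.append(vb)
    if len(xa) < min_overlap:
        raise ValueError(
            f"insufficient aligned profile overlap ({len(xa)} < {min_overlap})")
    r, _p = pearsonr(xa, xb)
    return float(r)
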