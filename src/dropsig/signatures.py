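"""Gene-signature algebra and probability-profile containers.

A *gene signature* is the presence/absence pattern of a fixed panel of M
marker transcripts in one droplet or one cell.  With M markers there are
G = 2**M possible signatures, indexed 1..G.  The index convention used
throughout the package is:

    index = 1 + sum_m bit_m * 2**(m-1)

i.e. marker 1 is the least-significant bit, index 1 is the all-negative
signature and index G is the all-positive one.  This convention is what
makes the droplet forward model (see :mod:`dropsig.deconvolve`)
reproducible: combining signatures 2 and 3 yields signature 4, combining
2 and 7 yields 8, and so on.

Signatures combine by marker-wise logical OR — a droplet containing a
cell with signature a and ambient RNA with signature b displays a OR b.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneSignature",
    "SignatureProfile",
    "MarkerPanel",
    "combine",
    "enumerate_signatures",
]

#: Largest supported marker-panel size; profiles are stored dense (2**M).
MAX_MARKERS = 16

#: Tolerance for requiring a profile to sum to one.
SUM_TOLERANCE = 1e-9


@dataclass(frozen=True)
class GeneSignature:
    """Presence/absence pattern over an ordered marker panel.

    Parameters
    ----------
    bits : tuple of bool
        ``bits[m]`` is True when marker ``m+1`` is positive.  Marker 1 is
        the least-significant bit of the index encoding.
    """

    bits: tuple[bool, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.bits) <= MAX_MARKERS:
            raise ValueError(
                f"number of markers must be in 1..{MAX_MARKERS}, got {len(self.bits)}"
            )
        object.__setattr__(self, "bits", tuple(bool(b) for b in self.bits))

    # -- encoding ------------------------------------------------------

    @property
    def n_markers(self) -> int:
        return len(self.bits)

    @property
    def mask(self) -> int:
        """Bitmask with marker m on bit m-1 (0 for all-negative)."""
        m = 0
        for i, b in enumerate(self.bits):
            if b:
                m |= 1 << i
        return m

    @property
    def index(self) -> int:
        """1-based signature index; 1 = all-negative, 2**M = all-positive."""
        return self.mask + 1

    @classmethod
    def from_index(cls, index: int, n_markers: int) -> "GeneSignature":
        g = 1 << n_markers
        if not 1 <= index <= g:
            raise ValueError(f"index must be in 1..{g} for M={n_markers}, got {index}")
        mask = index - 1
        return cls(tuple(bool(mask >> i & 1) for i in range(n_markers)))

    @classmethod
    def from_string(cls, text: str) -> "GeneSignature":
        """Parse the ``"+-+"`` string form (marker order = panel order)."""
        bits = []
        for ch in text.strip():
            if ch == "+":
                bits.append(True)
            elif ch == "-":
                bits.append(False)
            else:
                raise ValueError(f"signature string may contain only '+'/'-': {text!r}")
        return cls(tuple(bits))

    def to_string(self) -> str:
        return "".join("+" if b else "-" for b in self.bits)

    # -- algebra -------------------------------------------------------

    def __or__(self, other: "GeneSignature") -> "GeneSignature":
        if self.n_markers != other.n_markers:
            raise ValueError(
                f"cannot combine signatures over different panels "
                f"(M={self.n_markers} vs M={other.n_markers})"
            )
        return GeneSignature(tuple(a or b for a, b in zip(self.bits, other.bits)))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.to_string()


def combine(signatures: Sequence[GeneSignature], n_markers: int | None = None) -> GeneSignature:
    """Marker-wise OR of signatures (the signature a droplet displays).

    An empty list returns the all-negative signature, in which case
    ``n_markers`` must be given.
    """
    if len(signatures) == 0:
        if n_markers is None:
            raise ValueError("combine of an empty list needs n_markers")
        return GeneSignature((False,) * n_markers)
    out = signatures[0]
    for sig in signatures[1:]:
        out = out | sig
    return out


def enumerate_signatures(n_markers: int) -> list[GeneSignature]:
    """All 2**M signatures in index order (1 = all-negative first)."""
    if not 1 <= n_markers <= MAX_MARKERS:
        raise ValueError(f"n_markers must be in 1..{MAX_MARKERS}, got {n_markers}")
    g = 1 << n_markers
    return [GeneSignature.from_index(i, n_markers) for i in range(1, g + 1)]


class SignatureProfile:
    """Probability distribution over the G = 2**M gene signatures.

    Used in several roles: droplet profile ``d`` (cell-containing
    droplets), ambient profile ``n`` (empty droplets), single-cell
    profile ``s``, reference profile ``r_k`` of a pure population, and
    ambient mixture ``m``.

    Entries must be non-negative and sum to one within ``SUM_TOLERANCE``;
    pass ``renormalize=True`` for empirically estimated vectors whose sum
    drifts from one.
    """

    def __init__(
        self,
        values: Iterable[float],
        role: str | None = None,
        renormalize: bool = False,
    ) -> None:
        vals = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                          dtype=float)
        if vals.ndim != 1:
            raise ValueError("profile values must be a 1-D vector")
        g = vals.size
        m = int(g).bit_length() - 1
        if g < 2 or (1 << m) != g:
            raise ValueError(f"profile length must be a power of two >= 2, got {g}")
        if m > MAX_MARKERS:
            raise ValueError(f"profile implies M={m} > {MAX_MARKERS} markers")
        if not np.all(np.isfinite(vals)):
            raise ValueError("profile entries must be finite")
        if np.any(vals < 0):
            raise ValueError("profile entries must be non-negative")
        total = vals.sum()
        if renormalize:
            if total <= 0:
                raise ValueError("cannot renormalize a zero profile")
            vals = vals / total
        elif abs(total - 1.0) > SUM_TOLERANCE:
            raise ValueError(
                f"profile entries must sum to 1 (got {total!r}); "
                "pass renormalize=True for empirical estimates"
            )
        self._values = vals
        self._values.setflags(write=False)
        self.role = role

    # -- container protocol -------------------------------------------

    @property
    def values(self) -> np.ndarray:
        return self._values

    @property
    def n_signatures(self) -> int:
        return self._values.size

    @property
    def n_markers(self) -> int:
        return int(self._values.size).bit_length() - 1

    def __len__(self) -> int:
        return self._values.size

    def __getitem__(self, index: int) -> float:
        """1-based access by signature index (matches the field notation)."""
        if not 1 <= index <= self.n_signatures:
            raise IndexError(f"signature index must be in 1..{self.n_signatures}")
        return float(self._values[index - 1])

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        arr = np.asarray(self._values, dtype=dtype)
        return arr.copy() if copy else arr

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tag = f" role={self.role!r}" if self.role else ""
        return f"SignatureProfile(M={self.n_markers}{tag}, {np.round(self._values, 4)})"

    # -- constructors --------------------------------------------------

    @classmethod
    def delta(cls, index: int, n_markers: int, role: str | None = None) -> "SignatureProfile":
        """Point mass on one signature (1-based index)."""
        g = 1 << n_markers
        vals = np.zeros(g)
        vals[index - 1] = 1.0
        return cls(vals, role=role)

    @classmethod
    def from_counts(cls, counts: Iterable[float], role: str | None = None) -> "SignatureProfile":
        return cls(np.asarray(list(counts), dtype=float), role=role, renormalize=True)

    # -- CSV form ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        sigs = enumerate_signatures(self.n_markers)
        return pd.DataFrame(
            {"signature": [s.to_string() for s in sigs], "probability": self._values}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, role: str | None = None, renormalize: bool = False) -> "SignatureProfile":
        """Read a ``signature,probability`` CSV (signatures in string form).

        Rows may come in any order; every signature of the panel must be
        present exactly once.
        """
        df = pd.read_csv(path)
        for col in ("signature", "probability"):
            if col not in df.columns:
                raise ValueError(f"profile CSV is missing required column {col!r}")
        sigs = [GeneSignature.from_string(s) for s in df["signature"]]
        m_set = {s.n_markers for s in sigs}
        if len(m_set) != 1:
            raise ValueError("profile CSV mixes signatures of different lengths")
        m = m_set.pop()
        g = 1 << m
        vals = np.full(g, np.nan)
        for sig, p in zip(sigs, df["probability"]):
            vals[sig.index - 1] = p
        if np.isnan(vals).any():
            missing = [
                GeneSignature.from_index(i + 1, m).to_string()
                for i in np.flatnonzero(np.isnan(vals))
            ]
            raise ValueError(f"profile CSV is missing signatures: {missing}")
        return cls(vals, role=role, renormalize=renormalize)


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered marker panel plus the fluorescence-channel wiring.

    ``channel_map`` binds each marker to its probe channel; ``cell_channel``
    names the cell-tracking-dye (e.g. Calcein) channel used to call the
    presence of a cell.
    """

    markers: tuple[str, ...]
    channel_map: Mapping[str, str] = field(default_factory=dict)
    cell_channel: str = "calcein"

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker names must be unique")
        if not 1 <= len(self.markers) <= MAX_MARKERS:
            raise ValueError(f"panel must have 1..{MAX_MARKERS} markers")
        cmap = dict(self.channel_map) if self.channel_map else {m: m for m in self.markers}
        unknown = set(cmap) - set(self.markers)
        if unknown:
            raise ValueError(f"channel map names unknown markers: {sorted(unknown)}")
        missing = set(self.markers) - set(cmap)
        if missing:
            raise ValueError(f"markers without a channel: {sorted(missing)}")
        object.__setattr__(self, "channel_map", cmap)
        object.__setattr__(self, "markers", tuple(self.markers))

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_signatures(self) -> int:
        return 1 << len(self.markers)

    def marker_channels(self) -> list[str]:
        """Probe channels in marker (bit) order."""
        return [self.channel_map[m] for m in self.markers]


#: Default panel mirroring the murine marker set used for demonstrations.
DEFAULT_PANEL = MarkerPanel(
    markers=("gata3", "epcr", "il7ra"),
    channel_map={"gata3": "gata3", "epcr": "epcr", "il7ra": "il7ra"},
    cell_channel="calcein",
)
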