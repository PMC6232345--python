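"""Wavelet packet transform of voxel time series.

A wavelet packet transform (WPT) recursively splits a signal with a
quadrature-mirror low-pass/high-pass filter pair, applying *both* branches
at every node.  Depth ``d`` therefore yields ``2**d`` equal-width subbands,
and depths 0..6 together give 127 packet nodes.  Packets are addressed
as ``DdPp`` with positions ``p`` exposed in frequency (sequency) order, so
packet ``DdPp`` covers roughly ``[p, p + 1] * (fs / 2) / 2**d`` Hz.

The transform here is the periodized orthogonal WPT with the Daubechies
wavelet with 7 vanishing moments (filter length 14).  Non-power-of-two
signal lengths are handled by per-level ceil-halving (never truncation);
for lengths not divisible by ``2**depth`` the deepest levels are then
slightly redundant, but perfect reconstruction is preserved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "PacketAddress",
    "FilterPair",
    "PacketTree",
    "make_db7_filters",
    "wpt_decompose",
    "wpt_reconstruct",
    "packet_passband",
    "frequency_order_positions",
    "natural_position",
    "DEFAULT_WAVELET",
    "DEFAULT_MAX_DEPTH",
    "DEFAULT_MODE",
]

DEFAULT_WAVELET = "db7"
DEFAULT_MAX_DEPTH = 6
DEFAULT_MODE = "periodization"

_ADDR_RE = re.compile(r"^D(\d+)P(\d+)$")


@dataclass(frozen=True, order=True)
class PacketAddress:
    """Address of one wavelet packet node: depth and frequency-ordered position.

    ``depth=0, position=0`` is the input (broadband) signal; at depth ``d``
    position ``p`` runs over ``0 .. 2**d - 1`` from the lowest to the highest
    frequency band.
    """

    depth: int
    position: int

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if not 0 <= self.position <= 2**self.depth - 1:
            raise ValueError(
                f"position must lie in [0, {2**self.depth - 1}] at depth "
                f"{self.depth}, got {self.position}"
            )

    def __str__(self) -> str:
        return f"D{self.depth}P{self.position}"

    @classmethod
    def parse(cls, text: str) -> "PacketAddress":
        m = _ADDR_RE.match(text.strip())
        if m is None:
            raise ValueError(f"not a packet address: {text!r} (expected 'DdPp')")
        return cls(int(m.group(1)), int(m.group(2)))

    def passband(self, fs: float) -> tuple[float, float]:
        return packet_passband(self, fs)

    def is_ancestor_of(self, other: "PacketAddress") -> bool:
        """True if this node lies on the path from the root to ``other``.

        Ancestry follows the filter-bank recursion, i.e. it is defined on
        natural (paley) positions, where the parent of natural position
        ``q`` at depth ``d`` is ``q >> 1`` at depth ``d - 1``.
        """
        if self.depth >= other.depth:
            return False
        q_self = natural_position(self.depth, self.position)
        q_other = natural_position(other.depth, other.position)
        return (q_other >> (other.depth - self.depth)) == q_self


@dataclass(frozen=True)
class FilterPair:
    """Quadrature-mirror analysis filter pair (low-pass h, high-pass g)."""

    lowpass: np.ndarray
    highpass: np.ndarray
    name: str = "db7"

    def __len__(self) -> int:
        return len(self.lowpass)


def make_db7_filters() -> FilterPair:
    """Daubechies filters with 7 vanishing moments (length 14).

    The high-pass filter follows the alternating-flip convention
    ``g[n] = (-1)**n h[L-1-n]``; PyWavelets stores the same filter with the
    opposite global sign, which changes nothing measurable downstream
    (energies, correlations and reconstructions are sign-invariant).
    """
    h = np.asarray(pywt.Wavelet("db7").dec_lo, dtype=float)
    L = len(h)
    g = np.array([(-1) ** n * h[L - 1 - n] for n in range(L)])
    return FilterPair(lowpass=h, highpass=g, name="db7")


def frequency_order_positions(depth: int) -> np.ndarray:
    """Permutation mapping frequency order to natural filter-bank order.

    ``perm[k]`` is the natural (paley) position holding the ``k``-th lowest
    frequency band.  Because the high-pass branch mirrors the spectrum, the
    mapping is the binary-reflected Gray code ``k ^ (k >> 1)``; it is the
    identity at depths 0 and 1.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    k = np.arange(2**depth)
    return k ^ (k >> 1)


def natural_position(depth: int, position: int) -> int:
    """Natural (paley) position of the frequency-ordered ``position``."""
    return int(position ^ (position >> 1))


def packet_passband(address: PacketAddress, fs: float) -> tuple[float, float]:
    """Nominal passband of a packet in Hz: ``[p, p+1] * (fs/2) / 2**d``.

    Band edges are nominal: a finite filter leaks energy into the
    neighbouring bands, increasingly so at greater depth.
    """
    if fs <= 0:
        raise ValueError("sampling frequency must be positive")
    width = (fs / 2) / 2**address.depth
    return (address.position * width, (address.position + 1) * width)


def _node_lengths(n: int, max_depth: int) -> list[int]:
    """Per-depth coefficient length under ceil-halving."""
    lens = [n]
    for _ in range(max_depth):
        lens.append((lens[-1] + 1) // 2)
    return lens


@dataclass
class PacketTree:
    """Full wavelet packet tree of one or many time series.

    ``nodes`` maps each :class:`PacketAddress` (frequency-ordered) to a
    coefficient array whose trailing axis is the coefficient index; leading
    axes (e.g. a voxel axis) are carried through unchanged.  Contains every
    node for depths ``0 .. max_depth`` — ``2**(max_depth+1) - 1`` of them.
    """

    nodes: dict[PacketAddress, np.ndarray]
    source_length: int
    max_depth: int
    fs: float
    wavelet: str = DEFAULT_WAVELET
    mode: str = DEFAULT_MODE
    _lengths: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self._lengths:
            self._lengths = _node_lengths(self.source_length, self.max_depth)

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, address: PacketAddress | str) -> np.ndarray:
        if isinstance(address, str):
            address = PacketAddress.parse(address)
        return self.nodes[address]

    def addresses(self, depth: int | None = None) -> list[PacketAddress]:
        if depth is None:
            return sorted(self.nodes)
        return [PacketAddress(depth, p) for p in range(2**depth)]

    def passband(self, address: PacketAddress) -> tuple[float, float]:
        return packet_passband(address, self.fs)

    def reconstruct(self, keep) -> np.ndarray:
        return wpt_reconstruct(self, keep)


def wpt_decompose(
    series: np.ndarray,
    max_depth: int = DEFAULT_MAX_DEPTH,
    wavelet: str = DEFAULT_WAVELET,
    mode: str = DEFAULT_MODE,
    fs: float = 1.0,
) -> PacketTree:
    """Decompose time series into a full wavelet packet tree.

    Parameters
    ----------
    series
        Array with time on the last axis; any leading (voxel) axes are
        transformed independently and in a batch.
    max_depth
        Number of filter-bank levels; depths ``0..max_depth`` are returned.
    wavelet, mode
        PyWavelets wavelet name and signal-extension mode.  The default
        periodized transform is orthogonal, so per-depth energy equals the
        input energy whenever the signal length is divisible by
        ``2**max_depth``.
    fs
        Sampling frequency in Hz, recorded for passband computation.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    if n < 2**max_depth:
        raise ValueError(
            f"series length {n} too short for depth {max_depth}; "
            f"need at least {2**max_depth} samples"
        )
    levels: list[list[np.ndarray]] = [[series]]
    for _ in range(max_depth):
        nxt: list[np.ndarray] = []
        for node in levels[-1]:
            cA, cD = pywt.dwt(node, wavelet, mode=mode, axis=-1)
            nxt.append(cA)
            nxt.append(cD)
        levels.append(nxt)

    nodes: dict[PacketAddress, np.ndarray] = {}
    for d in range(max_depth + 1):
        perm = frequency_order_positions(d)
        for p in range(2**d):
            nodes[PacketAddress(d, p)] = levels[d][perm[p]]
    return PacketTree(
        nodes=nodes,
        source_length=n,
        max_depth=max_depth,
        fs=fs,
        wavelet=wavelet,
        mode=mode,
    )


def _check_non_overlapping(addresses: list[PacketAddress]) -> None:
    for i, a in enumerate(addresses):
        for b in addresses[i + 1 :]:
            if a == b:
                raise ValueError(f"duplicate packet address {a}")
            if a.is_ancestor_of(b) or b.is_ancestor_of(a):
                raise ValueError(
                    f"overlapping packet addresses: {a} and {b} "
                    "(one is an ancestor of the other)"
                )


def wpt_reconstruct(tree: PacketTree, keep) -> np.ndarray:
    """Inverse WPT keeping only the ``keep`` packets (others zeroed).

    ``keep`` is an iterable of :class:`PacketAddress` (or ``DdPp`` strings)
    that must be mutually non-overlapping in the tree.  The operation is
    linear in the kept coefficients; keeping every node of one depth
    reproduces the input signal.
    """
    keep_addrs = [
        PacketAddress.parse(a) if isinstance(a, str) else a for a in keep
    ]
    _check_non_overlapping(keep_addrs)
    for a in keep_addrs:
        if a not in tree.nodes:
            raise KeyError(f"packet {a} not present in tree (depth > {tree.max_depth}?)")

    lead_shape = tree.nodes[PacketAddress(0, 0)].shape[:-1]
    lens = tree._lengths
    if not keep_addrs:
        return np.zeros(lead_shape + (tree.source_length,))

    # natural-position lookup of kept coefficient arrays, deepest first
    kept_nat = {
        (a.depth, natural_position(a.depth, a.position)): tree.nodes[a]
        for a in keep_addrs
    }
    max_d = max(a.depth for a in keep_addrs)

    def subtree_nonzero(d: int, q: int) -> bool:
        span = 1
        for dd in range(d, max_d + 1):
            base = q * span
            if any((dd, base + j) in kept_nat for j in range(span)):
                return True
            span *= 2
        return False

    def rec(d: int, q: int) -> np.ndarray:
        if (d, q) in kept_nat:
            return np.ascontiguousarray(kept_nat[(d, q)])
        if d == max_d or not subtree_nonzero(d, q):
            return np.zeros(lead_shape + (lens[d],))
        a = rec(d + 1, 2 * q)
        b = rec(d + 1, 2 * q + 1)
        y = pywt.idwt(a, b, tree.wavelet, mode=tree.mode, axis=-1)
        return y[..., : lens[d]]

    return rec(0, 0)
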