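"""Residue windows around candidate cut sites and their one-hot encoding.

A candidate cut site is identified by the 1-based position of its P1
residue; the scissile bond lies between P1 and P1'.  A window of
``n_left`` residues ending at P1 and ``n_right`` residues after it is
encoded as a binary vector of length ``20 * (n_left + n_right)``: each
residue occupies a 20-element block with a single 1 marking the amino
acid (Ala at 0-based block index 4, Val at index 0).  Padding positions
beyond a protein terminus, and the relaxed-normalization placeholder,
encode as all-zero blocks carrying no information.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from .sequence_io import PLACEHOLDER, ProteinRecord

#: Frozen residue ordering defining each one-hot block.  Val maps to
#: index 0 and Ala to index 4; the remaining assignments are an arbitrary
#: frozen convention — any permutation yields an equivalent feature
#: space (one-hot blocks are symmetric under residue relabeling).
RESIDUE_ORDER = "VLIMAFWYGPSTCNQDEHKR"

RESIDUE_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(RESIDUE_ORDER)}

N_RESIDUES = 20

#: Window extents explored by the original optimization grid.
GRID_N_LEFT = (4, 6, 8, 10, 12, 14, 16)
GRID_N_RIGHT = (0, 2, 4, 6, 8, 10, 12, 14, 16)


class PaddingPolicy(str, Enum):
    """How to treat windows that overrun a protein terminus.

    ``SKIP`` drops the site (clean training sets); ``PAD`` fills
    out-of-range positions with the placeholder so near-terminal sites
    can still be scored when scanning whole proteomes.
    """

    SKIP = "skip"
    PAD = "pad"


class Label(int, Enum):
    POSITIVE = 1
    NEGATIVE = -1
    UNKNOWN = 0


@dataclass(frozen=True)
class WindowGeometry:
    """Window extent around the scissile bond.

    ``n_left`` residues end at P1 (P1 is the last of them); ``n_right``
    residues follow the cut.  Feature vectors have
    ``20 * (n_left + n_right)`` elements.
    """

    n_left: int
    n_right: int

    def __post_init__(self) -> None:
        if self.n_left < 1:
            raise ValueError("n_left must be >= 1 (the window must contain P1)")
        if self.n_right < 0:
            raise ValueError("n_right must be >= 0")

    @property
    def width(self) -> int:
        return self.n_left + self.n_right

    @property
    def n_features(self) -> int:
        return N_RESIDUES * self.width

    def __str__(self) -> str:  # e.g. "6-4", matching SVM-6-4 style names
        return f"{self.n_left}-{self.n_right}"


@dataclass(frozen=True)
class CandidateSite:
    """A potential cut site: protein + 1-based P1 position + label."""

    protein_id: str
    p1_position: int
    label: Label = Label.UNKNOWN

    def __post_init__(self) -> None:
        if self.p1_position < 1:
            raise ValueError("p1_position is 1-based and must be >= 1")


def extract_window(
    protein: ProteinRecord,
    site: CandidateSite,
    geom: WindowGeometry,
    padding_policy: PaddingPolicy = PaddingPolicy.SKIP,
) -> Optional[str]:
    """Extract the residue window around ``site``.

    Returns the window string of length ``geom.width`` (positions
    ``p1-n_left+1 .. p1`` followed by ``p1+1 .. p1+n_right``), or
    ``None`` when the window overruns a terminus under
    :attr:`PaddingPolicy.SKIP`.  Under :attr:`PaddingPolicy.PAD`
    out-of-range positions become the placeholder character.
    """
    seq = protein.sequence
    p1 = site.p1_position
    if not 1 <= p1 <= len(seq):
        raise ValueError(
            f"site position {p1} out of range for protein {protein.id!r} "
            f"of length {len(seq)}"
        )
    start = p1 - geom.n_left  # 0-based inclusive
    end = p1 + geom.n_right  # 0-based exclusive
    if start < 0 or end > len(seq):
        if padding_policy is PaddingPolicy.SKIP:
            return None
        left_pad = max(0, -start)
        right_pad = max(0, end - len(seq))
        core = seq[max(0, start) : min(end, len(seq))]
        return PLACEHOLDER * left_pad + core + PLACEHOLDER * right_pad
    return seq[start:end]


def encode(window: str, geom: Optional[WindowGeometry] = None) -> np.ndarray:
    """One-hot encode a residue window.

    Each residue becomes a 20-element indicator block following
    :data:`RESIDUE_INDEX`; the placeholder becomes an all-zero block.
    If ``geom`` is given the window length is checked against it.
    """
    if geom is not None and len(window) != geom.width:
        raise ValueError(
            f"window length {len(window)} does not match geometry {geom}"
        )
    vec = np.zeros(N_RESIDUES * len(window), dtype=np.float64)
    for i, aa in enumerate(window):
        if aa == PLACEHOLDER:
            continue
        try:
            j = RESIDUE_INDEX[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} at window position {i}")
        vec[N_RESIDUES * i + j] = 1.0
    return vec


def encode_windows(windows: Sequence[str]) -> np.ndarray:
    """Encode equal-length windows into a 2-D feature matrix."""
    if not windows:
        return np.zeros((0, 0), dtype=np.float64)
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("all windows must share one geometry")
    X = np.zeros((len(windows), N_RESIDUES * width), dtype=np.float64)
    for r, w in enumerate(windows):
        for i, aa in enumerate(w):
            if aa == PLACEHOLDER:
                continue
            try:
                X[r, N_RESIDUES * i + RESIDUE_INDEX[aa]] = 1.0
            except KeyError:
                raise ValueError(f"unknown residue {aa!r} in window {w!r}")
    return X


def decode(vec: np.ndarray) -> str:
    """Inverse of :func:`encode`; all-zero blocks decode to the placeholder."""
    if vec.size % N_RESIDUES:
        raise ValueError("vector length must be a multiple of 20")
    blocks = np.asarray(vec).reshape(-1, N_RESIDUES)
    out = []
    for block in blocks:
        hits = np.flatnonzero(block)
        if hits.size == 0:
            out.append(PLACEHOLDER)
        elif hits.size == 1:
            out.append(RESIDUE_ORDER[hits[0]])
        else:
            raise ValueError("block has more than one set element")
    return "".join(out)


class Motif:
    """A P1-anchored residue pattern restricting candidate positions.

    The pattern covers the last ``len(pattern)`` residues up to and
    including P1 (so ``"D"`` means Asp at P1; ``"DEVD"`` constrains
    P4–P1).  Each pattern position is either one residue or an
    IUPAC-style character class in brackets, e.g. ``"[WL]EHD"``.
    ``"X"`` matches any residue.
    """

    def __init__(self, pattern: str = "D"):
        self.pattern = pattern
        self._positions: list[frozenset[str]] = []
        for m in re.finditer(r"\[([A-Z]+)\]|([A-Z])", pattern):
            chars = m.group(1) or m.group(2)
            if chars == "X":
                self._positions.append(frozenset("ACDEFGHIKLMNPQRSTVWY"))
            else:
                self._positions.append(frozenset(chars))
        if not self._positions:
            raise ValueError(f"empty motif pattern {pattern!r}")

    def __len__(self) -> int:
        return len(self._positions)

    def matches_at(self, sequence: str, p1_position: int) -> bool:
        """True when the pattern matches ending at 1-based ``p1_position``."""
        k = len(self._positions)
        start = p1_position - k  # 0-based index of first pattern residue
        if start < 0:
            return False
        for cls, aa in zip(self._positions, sequence[start:p1_position]):
            if aa not in cls:
                return False
        return True

    def __repr__(self) -> str:
        return f"Motif({self.pattern!r})"


def scan_candidates(
    protein: ProteinRecord,
    motif: Optional[Motif] = Motif("D"),
    geom: Optional[WindowGeometry] = None,
    padding_policy: PaddingPolicy = PaddingPolicy.PAD,
) -> list[CandidateSite]:
    """Enumerate candidate cut sites along a protein.

    With a motif only positions whose P1-anchored context matches are
    emitted (default: Asp at P1); with ``motif=None`` every residue
    position is a candidate.  When ``geom`` is given and the policy is
    SKIP, sites whose window would overrun a terminus are dropped.
    """
    sites = []
    for p1 in range(1, len(protein.sequence) + 1):
        if motif is not None and not motif.matches_at(protein.sequence, p1):
            continue
        site = CandidateSite(protein.id, p1)
        if geom is not None and padding_policy is PaddingPolicy.SKIP:
            if extract_window(protein, site, geom, PaddingPolicy.SKIP) is None:
                continue
        sites.append(site)
    return sites
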