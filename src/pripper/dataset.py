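"""Labeled training-set assembly and synthetic corpus generation.

Positives are annotated caspase cut sites (1-based P1 positions);
negatives are drawn from Asp positions in the same proteins that are not
annotated as cut.  The default negative policy is *balanced* — as many
negatives as positives, sampled uniformly with a seed — with an
*exhaustive* mode keeping every eligible Asp.  Duplicate windows are
removed so every training sequence is unique.

The synthetic generator plants P4–P1 motifs from the three canonical
caspase recognition classes — (W/L)EHD for caspases 1/4/5/13, DEXD for
caspases 2/3/7, and (I/L/V)E(H/T)D for caspases 6/8/9/10 — into
i.i.d.-uniform background sequence, and enriches the P1' position for
small residues (G/A/S), giving classifiers a learnable signal on both
sides of the scissile bond.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .encoding import (
    CandidateSite,
    Label,
    Motif,
    PaddingPolicy,
    WindowGeometry,
    encode_windows,
    extract_window,
)
from .sequence_io import ProteinRecord, read_fasta, read_known_sites

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Recognition-motif classes: name -> (per-position residue choices for
#: P4 P3 P2 P1).  "X" stands for any residue.
MOTIF_CLASSES: dict[str, tuple[str, str, str, str]] = {
    "WEHD": ("WL", "E", "H", "D"),
    "DEXD": ("D", "E", "X", "D"),
    "IETD": ("ILV", "E", "HT", "D"),
}

#: Default class mix: the DEXD class (executioner caspases 3/7) is the
#: best-characterized and dominates curated substrate sets.
DEFAULT_CLASS_PROBS: dict[str, float] = {"WEHD": 0.25, "DEXD": 0.50, "IETD": 0.25}


@dataclass
class LabeledDataset:
    """Encoded candidate sites with ±1 labels at one window geometry."""

    X: np.ndarray
    y: np.ndarray
    geometry: WindowGeometry
    sites: list[CandidateSite] = field(default_factory=list)
    windows: list[str] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if self.X.shape[0] and not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("labels must be +1 or -1")
        if self.X.shape[0] and self.X.shape[1] != self.geometry.n_features:
            raise ValueError(
                f"feature width {self.X.shape[1]} does not match geometry "
                f"{self.geometry} ({self.geometry.n_features} features)"
            )

    def __len__(self) -> int:
        return int(self.X.shape[0])

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.y == 1))

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.y == -1))

    def subset(self, indices: Sequence[int], provenance: str = "") -> "LabeledDataset":
        idx = np.asarray(indices, dtype=np.intp)
        return LabeledDataset(
            X=self.X[idx],
            y=self.y[idx],
            geometry=self.geometry,
            sites=[self.sites[i] for i in idx] if self.sites else [],
            windows=[self.windows[i] for i in idx] if self.windows else [],
            provenance=provenance or self.provenance,
        )


def assemble_sites(
    proteins: Sequence[ProteinRecord],
    positive_sites: Mapping[str, Sequence[int]],
    *,
    negative_policy: str = "balanced",
    n_negatives: Optional[int] = None,
    seed: Optional[int] = None,
    motif: Optional[Motif] = Motif("D"),
    on_motif_conflict: str = "warn",
) -> list[CandidateSite]:
    """Label candidate sites: annotated positives + non-cut-Asp negatives.

    ``negative_policy`` is ``"balanced"`` (sample as many negatives as
    positives, uniformly, seeded) or ``"exhaustive"`` (keep every
    eligible motif position).  A positive position whose residue
    conflicts with the motif's P1 is warned about and dropped
    (``on_motif_conflict="reject"`` raises instead).
    """
    if negative_policy not in ("balanced", "exhaustive"):
        raise ValueError(f"unknown negative policy {negative_policy!r}")
    by_id = {p.id: p for p in proteins}
    positives: list[CandidateSite] = []
    for pid, positions in positive_sites.items():
        if pid not in by_id:
            raise KeyError(f"positive sites reference unknown protein {pid!r}")
        seq = by_id[pid].sequence
        for p1 in positions:
            if not 1 <= p1 <= len(seq):
                raise ValueError(
                    f"positive site {p1} out of range for protein {pid!r}"
                )
            if motif is not None and not motif.matches_at(seq, p1):
                msg = (
                    f"positive site {pid}:{p1} (residue {seq[p1 - 1]!r}) does "
                    f"not match motif {motif.pattern!r}"
                )
                if on_motif_conflict == "reject":
                    raise ValueError(msg)
                warnings.warn(msg)
                continue
            positives.append(CandidateSite(pid, p1, Label.POSITIVE))

    pos_keys = {(s.protein_id, s.p1_position) for s in positives}
    eligible: list[CandidateSite] = []
    neg_motif = motif if motif is not None else Motif("D")
    for prot in proteins:
        for p1 in range(1, len(prot.sequence) + 1):
            if not neg_motif.matches_at(prot.sequence, p1):
                continue
            if (prot.id, p1) in pos_keys:
                continue
            eligible.append(CandidateSite(prot.id, p1, Label.NEGATIVE))

    if negative_policy == "exhaustive":
        negatives = eligible
    else:
        want = len(positives) if n_negatives is None else n_negatives
        if want >= len(eligible):
            negatives = eligible
        else:
            rng = np.random.default_rng(seed)
            pick = rng.choice(len(eligible), size=want, replace=False)
            negatives = [eligible[i] for i in sorted(pick)]
    return positives + negatives


def build_dataset(
    proteins: Sequence[ProteinRecord],
    positive_sites: Mapping[str, Sequence[int]],
    geom: WindowGeometry,
    *,
    negative_policy: str = "balanced",
    seed: Optional[int] = None,
    padding_policy: PaddingPolicy = PaddingPolicy.SKIP,
    motif: Optional[Motif] = Motif("D"),
    provenance: str = "",
    sites: Optional[Sequence[CandidateSite]] = None,
    on_contradiction: str = "drop",
) -> LabeledDataset:
    """Assemble and encode a labeled dataset at one window geometry.

    Windows that overrun a terminus are dropped under the default SKIP
    policy.  Duplicate windows are removed (every training sequence is
    unique).  A window occurring with both labels is contradictory: by
    default the later occurrence is dropped with a warning (an annotated
    positive always precedes the colliding negative, so positives win);
    ``on_contradiction="error"`` makes it fatal instead.  Pass ``sites``
    to reuse one labeled site list across several geometries (as the
    Vote ensemble needs).
    """
    if on_contradiction not in ("drop", "error"):
        raise ValueError(f"unknown contradiction policy {on_contradiction!r}")
    by_id = {p.id: p for p in proteins}
    if sites is None:
        sites = assemble_sites(
            proteins,
            positive_sites,
            negative_policy=negative_policy,
            seed=seed,
            motif=motif,
        )
    kept_sites: list[CandidateSite] = []
    kept_windows: list[str] = []
    labels: list[int] = []
    seen: dict[str, int] = {}
    for site in sites:
        if site.label is Label.UNKNOWN:
            raise ValueError("all sites must be labeled for training")
        window = extract_window(by_id[site.protein_id], site, geom, padding_policy)
        if window is None:
            continue
        lab = int(site.label)
        if window in seen:
            if seen[window] != lab:
                msg = (
                    f"window {window!r} appears with both labels "
                    f"(contradictory training data)"
                )
                if on_contradiction == "error":
                    raise ValueError(msg)
                warnings.warn(msg + "; dropping the later occurrence")
            continue
        seen[window] = lab
        kept_sites.append(site)
        kept_windows.append(window)
        labels.append(lab)
    X = encode_windows(kept_windows)
    if not kept_windows:
        X = np.zeros((0, geom.n_features))
    return LabeledDataset(
        X=X,
        y=np.asarray(labels, dtype=np.int64),
        geometry=geom,
        sites=kept_sites,
        windows=kept_windows,
        provenance=provenance,
    )


def generate_synthetic_corpus(
    n_proteins: int = 360,
    length_range: tuple[int, int] = (120, 400),
    *,
    motif_spec: Optional[Mapping[str, float]] = None,
    planting_rate: float = 1.25,
    p1prime_small_rate: float = 0.6,
    seed: Optional[int] = None,
    terminal_margin: int = 16,
    max_retries: int = 200,
    return_classes: bool = False,
) -> tuple[list[ProteinRecord], dict[str, list[int]]]:
    """Generate proteins with planted caspase cut sites.

    Background residues are i.i.d. uniform over the 20 amino acids.
    Each protein receives a Poisson(``planting_rate``) number of planted
    sites; each plant writes a P4–P1 motif drawn from ``motif_spec``
    (default :data:`DEFAULT_CLASS_PROBS`) ending at the P1 position, and
    with probability ``p1prime_small_rate`` sets P1' to a small residue
    (G/A/S).  Plants stay ``terminal_margin`` residues away from both
    termini so every grid geometry can see them, and overlapping plants
    are re-drawn (bounded retries).  Deterministic under ``seed``.

    Returns ``(proteins, positive_sites)`` with positions 1-based; with
    ``return_classes=True`` a third element maps ``(protein_id, p1)`` to
    the drawn motif-class name (classes overlap in sequence space —
    LEHD belongs to two — so frequency audits need the drawn class).
    """
    probs = dict(motif_spec) if motif_spec is not None else dict(DEFAULT_CLASS_PROBS)
    names = sorted(probs)
    weights = np.array([probs[n] for n in names], dtype=float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("motif class probabilities must be nonnegative, sum > 0")
    weights = weights / weights.sum()
    lo, hi = length_range
    if lo < 2 * terminal_margin + 8:
        raise ValueError(
            f"minimum protein length {lo} too short for terminal margin "
            f"{terminal_margin}"
        )
    rng = np.random.default_rng(seed)
    aas = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    small = "GAS"

    proteins: list[ProteinRecord] = []
    positive_sites: dict[str, list[int]] = {}
    site_classes: dict[tuple[str, int], str] = {}
    for k in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        residues = aas[rng.integers(0, 20, size=length)].tobytes().decode()
        seq = list(residues)
        n_sites = int(rng.poisson(planting_rate))
        placed: list[int] = []
        for _ in range(n_sites):
            for _attempt in range(max_retries):
                p1 = int(rng.integers(terminal_margin + 1, length - terminal_margin + 1))
                # plants occupy P4..P1' = p1-3 .. p1+1; keep them disjoint
                if all(abs(p1 - q) > 4 for q in placed):
                    break
            else:
                raise RuntimeError(
                    f"could not place {n_sites} non-overlapping sites in a "
                    f"length-{length} protein after {max_retries} retries"
                )
            cls = names[int(rng.choice(len(names), p=weights))]
            motif = "".join(
                choice[int(rng.integers(0, len(choice)))]
                if choice != "X"
                else AMINO_ACIDS[int(rng.integers(0, 20))]
                for choice in MOTIF_CLASSES[cls]
            )
            seq[p1 - 4 : p1] = motif
            if rng.random() < p1prime_small_rate:
                seq[p1] = small[int(rng.integers(0, len(small)))]
            placed.append(p1)
            site_classes[(f"syn{k:05d}", p1)] = cls
        pid = f"syn{k:05d}"
        proteins.append(ProteinRecord(id=pid, sequence="".join(seq)))
        if placed:
            positive_sites[pid] = sorted(placed)
    if return_classes:
        return proteins, positive_sites, site_classes
    return proteins, positive_sites


def split_dataset(
    ds: LabeledDataset, fraction: float, seed: Optional[int] = None
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified split into (train, test) with ``fraction`` in train.

    Disjoint, union equals the dataset; class balance is preserved to
    rounding.  Deterministic under ``seed``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be strictly between 0 and 1")
    for cls in (-1, 1):
        if int(np.sum(ds.y == cls)) < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
    from sklearn.model_selection import train_test_split

    idx = np.arange(len(ds))
    train_idx, test_idx = train_test_split(
        idx, train_size=fraction, stratify=ds.y, random_state=seed
    )
    return (
        ds.subset(np.sort(train_idx), provenance=f"{ds.provenance}[train]"),
        ds.subset(np.sort(test_idx), provenance=f"{ds.provenance}[test]"),
    )


def load_training_set(
    fasta_path: Union[str, Path], sites_path: Union[str, Path]
) -> tuple[list[ProteinRecord], dict[str, list[int]]]:
    """Load a curated training set: protein FASTA + TSV of P1 positions.

    The TSV uses the known-sites format (``id<TAB>pos,pos,...``).  Use
    this to train on a published cut-site collection instead of the
    synthetic corpus.
    """
    proteins = read_fasta(fasta_path)
    known = read_known_sites(sites_path)
    by_id = {p.id for p in proteins}
    missing = sorted(set(known) - by_id)
    if missing:
        raise KeyError(f"site list references proteins absent from FASTA: {missing}")
    return proteins, {pid: list(ks.cut_positions) for pid, ks in known.items()}
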