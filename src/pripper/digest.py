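"""Proteome digestion: predict cut sites and emit cleavage-product FASTA.

Three output modes control which fragments a protein's predicted (or
user-supplied) cut positions produce:

* ``single_site`` — each site is cut on its own: fragments ``[1..p]``
  and ``[p+1..L]`` per site (matches the observation that a substrate
  is cleaved at one site at a time).
* ``all_sites`` — every site cut simultaneously: the k+1 consecutive
  fragments between adjacent cuts.
* ``all_combinations`` — every fragment reachable by some subset of the
  cuts: all spans ``[a..b]`` whose boundaries ``a−1`` and ``b`` are each
  a cut position or a terminus.

Identical spans arising from different cut subsets are emitted once;
fragment headers carry parent id, span, the cut positions used and
their P4–P1 contexts so MS identifications trace back to the sites.
Proteins listed in a known-sites file bypass prediction entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence, Union

import numpy as np

from .classifiers import SiteClassifier, VoteClassifier
from .encoding import (
    CandidateSite,
    Motif,
    PaddingPolicy,
    encode_windows,
    extract_window,
    scan_candidates,
)
from .sequence_io import KnownSiteList, ProteinRecord, iter_fasta, write_fasta

MODES = ("single_site", "all_sites", "all_combinations")


@dataclass(frozen=True)
class DigestOptions:
    """Digestion behavior: output mode, motif, filters."""

    mode: str = "single_site"
    include_full_sequence: bool = False
    motif: Optional[Motif] = field(default_factory=lambda: Motif("D"))
    min_fragment_length: int = 1
    padding_policy: PaddingPolicy = PaddingPolicy.PAD

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.min_fragment_length < 1:
            raise ValueError("min_fragment_length must be >= 1")


@dataclass(frozen=True)
class CleavageProduct:
    """A fragment of a parent protein delimited by cuts and/or termini."""

    parent_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    sequence: str
    cut_positions_used: tuple[int, ...] = ()
    motif_context: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("invalid fragment span")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length does not match span")

    @property
    def id(self) -> str:
        return self.header()

    def header(self) -> str:
        cuts = ",".join(str(p) for p in self.cut_positions_used)
        motifs = ",".join(self.motif_context)
        return (
            f"{self.parent_id}|frag|{self.start}-{self.end}"
            f"|cut:{cuts}|motif:{motifs}"
        )


def predict_sites(
    protein: ProteinRecord,
    clf: Union[SiteClassifier, VoteClassifier],
    opts: DigestOptions = DigestOptions(),
) -> list[int]:
    """Predicted P1 cut positions of one protein, sorted ascending.

    Candidates come from the motif scan (default: every Asp); each is
    classified, batched per geometry for speed.  Equivalent to mapping
    ``classify`` over ``scan_candidates`` output.
    """
    sites = scan_candidates(protein, opts.motif)
    if not sites:
        return []
    if isinstance(clf, VoteClassifier):
        labels = clf.predict_sites(protein, sites, opts.padding_policy)
    else:
        windows = []
        resolved = []
        for j, site in enumerate(sites):
            w = extract_window(protein, site, clf.geometry, opts.padding_policy)
            if w is None:
                continue
            windows.append(w)
            resolved.append(j)
        labels_part = clf.classify(encode_windows(windows)) if windows else []
        labels = np.full(len(sites), -1, dtype=np.int64)
        for j, lab in zip(resolved, labels_part):
            labels[j] = lab
    return sorted(s.p1_position for s, lab in zip(sites, labels) if lab == 1)


def apply_known_sites(protein: ProteinRecord, known: KnownSiteList) -> list[int]:
    """Use a user-supplied site list verbatim, bypassing prediction."""
    for p in known.cut_positions:
        if not 1 <= p <= len(protein.sequence):
            raise ValueError(
                f"known cut site {p} out of range for protein "
                f"{protein.id!r} (length {len(protein.sequence)})"
            )
    return list(known.cut_positions)


def _motif_context(sequence: str, p1: int) -> str:
    """P4–P1 context of a cut (shorter near the N-terminus)."""
    return sequence[max(0, p1 - 4) : p1]


def fragment(
    protein: ProteinRecord,
    cut_positions: Sequence[int],
    mode: str,
    *,
    min_fragment_length: int = 1,
) -> list[CleavageProduct]:
    """Fragments of ``protein`` for the given cuts under one output mode.

    Cut positions are 1-based P1 indices, sorted ascending, each in
    ``[1, L]``; a cut at L is legal but adds no boundary beyond the
    C-terminus.  With no cuts every mode yields no fragments (the intact
    sequence is the caller's include-full-sequence concern).  Spans are
    deduplicated: one product per distinct (start, end).
    """
    if mode not in MODES:
        raise ValueError(f"unknown digestion mode {mode!r}")
    L = len(protein.sequence)
    cuts = list(cut_positions)
    if cuts != sorted(set(cuts)):
        raise ValueError("cut positions must be sorted and unique")
    if cuts and not (1 <= cuts[0] and cuts[-1] <= L):
        raise ValueError(f"cut positions out of range 1..{L}")
    if not cuts:
        return []

    spans: list[tuple[int, int]] = []  # (start, end), 1-based inclusive
    if mode == "single_site":
        for p in cuts:
            spans.append((1, p))
            if p < L:
                spans.append((p + 1, L))
    elif mode == "all_sites":
        bounds = [0] + [p for p in cuts if p < L] + [L]
        spans = [(a + 1, b) for a, b in zip(bounds, bounds[1:])]
    else:  # all_combinations
        lowers = [0] + cuts
        uppers = cuts + [L]
        for a in lowers:
            for b in uppers:
                if b > a:
                    spans.append((a + 1, b))

    seen: set[tuple[int, int]] = set()
    products: list[CleavageProduct] = []
    cutset = set(cuts)
    for start, end in spans:
        if (start, end) in seen:
            continue
        seen.add((start, end))
        if end - start + 1 < min_fragment_length:
            continue
        used = tuple(p for p in (start - 1, end) if p in cutset)
        products.append(
            CleavageProduct(
                parent_id=protein.id,
                start=start,
                end=end,
                sequence=protein.sequence[start - 1 : end],
                cut_positions_used=used,
                motif_context=tuple(
                    _motif_context(protein.sequence, p) for p in used
                ),
            )
        )
    return products


@dataclass
class DigestSummary:
    """Per-run digestion statistics (the proteome-census numbers)."""

    proteins_processed: int = 0
    proteins_with_cut: int = 0
    total_cuts: int = 0
    products_written: int = 0
    records_skipped: int = 0

    @property
    def fraction_proteins_cut(self) -> float:
        if self.proteins_processed == 0:
            return 0.0
        return self.proteins_with_cut / self.proteins_processed

    @property
    def mean_cuts_per_cut_protein(self) -> float:
        if self.proteins_with_cut == 0:
            return 0.0
        return self.total_cuts / self.proteins_with_cut

    def to_tsv(self) -> str:
        rows = [
            ("proteins_processed", self.proteins_processed),
            ("proteins_with_cut", self.proteins_with_cut),
            ("percent_proteins_cut", round(100 * self.fraction_proteins_cut, 2)),
            ("total_cuts", self.total_cuts),
            ("mean_cuts_per_cut_protein", round(self.mean_cuts_per_cut_protein, 3)),
            ("products_written", self.products_written),
            ("records_skipped", self.records_skipped),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def digest_proteome(
    fasta_in: Union[str, Path],
    clf: Union[SiteClassifier, VoteClassifier],
    opts: DigestOptions = DigestOptions(),
    fasta_out: Union[str, Path] = "products.fasta",
    *,
    known_sites: Optional[Mapping[str, KnownSiteList]] = None,
    lenient: bool = False,
) -> DigestSummary:
    """Digest a whole proteome FASTA into a cleavage-product database.

    Streams one protein at a time, so memory is bounded by the largest
    protein, not the proteome.  Proteins present in ``known_sites``
    never reach the classifier.  With ``lenient=True`` per-record
    failures (invalid sequences, out-of-range known sites) are logged
    and skipped instead of aborting.
    """
    known_sites = known_sites or {}
    summary = DigestSummary()

    def stream() -> Iterator:
        for protein in iter_fasta(fasta_in, relaxed=lenient, lenient=lenient):
            try:
                if protein.id in known_sites:
                    cuts = apply_known_sites(protein, known_sites[protein.id])
                else:
                    cuts = predict_sites(protein, clf, opts)
                products = fragment(
                    protein,
                    cuts,
                    opts.mode,
                    min_fragment_length=opts.min_fragment_length,
                )
            except (ValueError, RuntimeError) as exc:
                if not lenient:
                    raise
                warnings.warn(f"skipping protein {protein.id!r}: {exc}")
                summary.records_skipped += 1
                continue
            summary.proteins_processed += 1
            if cuts:
                summary.proteins_with_cut += 1
                summary.total_cuts += len(cuts)
            for prod in products:
                summary.products_written += 1
                yield prod
            if opts.include_full_sequence:
                summary.products_written += 1
                yield ProteinRecord(
                    id=f"{protein.id}|full|1-{len(protein.sequence)}",
                    sequence=protein.sequence,
                )

    write_fasta(stream(), fasta_out)
    return summary


def summary_from_fasta(products_path: Union[str, Path]) -> DigestSummary:
    """Recompute cut statistics by re-parsing a product FASTA's headers.

    Counts distinct parents, distinct cut positions per parent, and
    products.  Full-sequence records (``|full|``) do not contribute
    cuts.  Useful as an independent audit of :func:`digest_proteome`'s
    summary (parents that produced no products are invisible here).
    """
    parents: dict[str, set[int]] = {}
    products = 0
    for rec in iter_fasta(products_path):
        products += 1
        parts = rec.id.split("|")
        parent = parts[0]
        parents.setdefault(parent, set())
        if len(parts) >= 4 and parts[1] == "frag":
            cut_field = next(
                (p for p in parts if p.startswith("cut:")), "cut:"
            )[len("cut:"):]
            for tok in cut_field.split(","):
                if tok:
                    parents[parent].add(int(tok))
    summary = DigestSummary(
        proteins_processed=len(parents),
        proteins_with_cut=sum(1 for s in parents.values() if s),
        total_cuts=sum(len(s) for s in parents.values()),
        products_written=products,
    )
    return summary
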