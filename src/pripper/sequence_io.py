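"""Protein FASTA input/output and known-cut-site lists.

Proteins are plain amino-acid sequences over the 20 standard one-letter
codes.  Cleavage products written by :mod:`pripper.digest` carry a
structured header so that a downstream MS identification can be traced
back to the predicted cut site::

    >{parent_id}|frag|{start}-{end}|cut:{p1,p1,...}|motif:{P4P3P2P1;...}

Known cut sites are supplied as a TSV file, one protein per line:
``protein_id<TAB>p1,p1,...`` with 1-based P1 positions (the cut falls
immediately C-terminal to P1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids, one-letter codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Codes seen in real databases that are not standard residues.
NONSTANDARD_AA = frozenset("BZXUO*")

#: Placeholder used for relaxed normalization and terminal padding;
#: encodes as an all-zero one-hot block (no information).
PLACEHOLDER = "-"


class FastaValidationError(ValueError):
    """A FASTA entry violates the protein-sequence contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its FASTA identity.

    Parameters
    ----------
    id : str
        First whitespace-delimited token of the FASTA header.
    sequence : str
        Upper-case amino-acid sequence, length >= 1.
    description : str
        Remainder of the header line (may be empty).
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise FastaValidationError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class KnownSiteList:
    """User-supplied cut sites for one protein.

    ``cut_positions`` are 1-based indices of P1 residues, strictly
    increasing.  Range checking against the protein happens at digestion
    time, when the protein sequence is in hand.
    """

    protein_id: str
    cut_positions: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        pos = self.cut_positions
        if any(p < 1 for p in pos):
            raise ValueError(
                f"known sites for {self.protein_id!r}: positions must be >= 1"
            )
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(
                f"known sites for {self.protein_id!r}: positions must be "
                "strictly increasing with no duplicates"
            )


def _normalize_sequence(
    raw: str, header: str, relaxed: bool, placeholder: str
) -> str:
    seq = "".join(raw.split()).upper()
    if not seq:
        raise FastaValidationError(f"empty sequence for FASTA entry {header!r}")
    bad = [(i + 1, c) for i, c in enumerate(seq) if c not in STANDARD_AA]
    if not bad:
        return seq
    if relaxed:
        table = str.maketrans({c: placeholder for _, c in bad})
        return seq.translate(table)
    pos, char = bad[0]
    raise FastaValidationError(
        f"FASTA entry {header!r}: disallowed residue {char!r} at position {pos} "
        "(use relaxed=True to map non-standard codes to the placeholder)"
    )


def read_fasta(
    path: Union[str, Path],
    *,
    relaxed: bool = False,
    placeholder: str = PLACEHOLDER,
) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Sequences are upper-cased with all whitespace removed; records keep
    file order.  By default any residue outside the 20-letter alphabet
    raises :class:`FastaValidationError`; with ``relaxed=True`` the
    non-standard codes (B, Z, X, U, O, ``*``) are mapped to
    ``placeholder``, which later encodes as an uninformative all-zero
    block.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalize_sequence(str(rec.seq), rec.id, relaxed, placeholder)
        records.append(
            ProteinRecord(id=rec.id, sequence=seq, description=rec.description)
        )
    return records


def iter_fasta(
    path: Union[str, Path],
    *,
    relaxed: bool = False,
    placeholder: str = PLACEHOLDER,
    lenient: bool = False,
) -> Iterator[ProteinRecord]:
    """Stream records one at a time (memory bounded by one protein).

    With ``lenient=True`` entries that fail validation are skipped with
    a warning instead of aborting the whole run.
    """
    for rec in SeqIO.parse(str(Path(path)), "fasta"):
        try:
            seq = _normalize_sequence(str(rec.seq), rec.id, relaxed, placeholder)
        except FastaValidationError:
            if lenient:
                warnings.warn(f"skipping invalid FASTA entry {rec.id!r}")
                continue
            raise
        yield ProteinRecord(id=rec.id, sequence=seq, description=rec.description)


def write_fasta(records: Iterable, path: Union[str, Path], *, width: int = 60) -> None:
    """Write protein records or cleavage products to FASTA.

    Accepts anything with ``id`` and ``sequence`` attributes (and an
    optional ``header()`` method, used by cleavage products to embed
    provenance).  Output wraps at ``width`` columns and round-trips
    through :func:`read_fasta` with identical ids and sequences.
    """

    def to_seqrecord(rec) -> SeqRecord:
        if hasattr(rec, "header"):
            head = rec.header()
            token, _, desc = head.partition(" ")
            return SeqRecord(Seq(rec.sequence), id=token, description=desc)
        return SeqRecord(Seq(rec.sequence), id=rec.id, description=rec.description)

    path = Path(path)
    with path.open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(to_seqrecord(r) for r in records)


class KnownSitesParseError(ValueError):
    """A known-sites TSV line could not be parsed."""


def read_known_sites(path: Union[str, Path]) -> dict[str, KnownSiteList]:
    """Parse a known-cut-sites TSV into ``{protein_id: KnownSiteList}``.

    Format: one protein per line, ``id<TAB>comma-separated 1-based P1
    positions``.  Positions are sorted; duplicates are collapsed with a
    warning.  An id with an empty position list is allowed and means
    "do not cut this protein" (it still bypasses prediction).
    """
    path = Path(path)
    out: dict[str, KnownSiteList] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) > 2 or not parts[0].strip():
                raise KnownSitesParseError(
                    f"{path.name}:{lineno}: expected 'id<TAB>pos,pos,...', got {line!r}"
                )
            pid = parts[0].strip()
            raw = parts[1].strip() if len(parts) == 2 else ""
            positions: list[int] = []
            if raw:
                for tok in raw.split(","):
                    tok = tok.strip()
                    try:
                        positions.append(int(tok))
                    except ValueError as exc:
                        raise KnownSitesParseError(
                            f"{path.name}:{lineno}: bad position {tok!r}"
                        ) from exc
            unique = sorted(set(positions))
            if len(unique) != len(positions):
                warnings.warn(
                    f"{path.name}:{lineno}: duplicate positions collapsed for {pid!r}"
                )
            if pid in out:
                raise KnownSitesParseError(
                    f"{path.name}:{lineno}: duplicate protein id {pid!r}"
                )
            out[pid] = KnownSiteList(protein_id=pid, cut_positions=tuple(unique))
    return out
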