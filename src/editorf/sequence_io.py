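"""Sequence input/output and the coordinate conventions used package-wide.

All coordinates in this package are 1-based and inclusive, measured on the
*scanned* strand: forward-strand ORFs carry forward coordinates, reverse-strand
ORFs carry coordinates within the reverse-complemented sequence.  A derived
forward-reference interval (``fwd_interval``) is attached to every candidate so
that overlap classification can work on a single axis.

Genome topology is recorded as metadata only; sequences are always scanned as
linear molecules and no wrap-around ORFs are produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, TextIO, Union

from Bio import SeqIO

VALID_CHARS = frozenset("acgtn")

Topology = Literal["linear", "circular"]


class SequenceError(ValueError):
    """Raised for unreadable, empty or invalid-alphabet sequence input."""


@dataclass(frozen=True)
class GenomeSequence:
    """A normalized nucleotide sequence (lower-case, alphabet {a,c,g,t,n}).

    Parameters
    ----------
    id : str
        Record identifier (e.g. an accession).
    residues : str
        Nucleotide string; validated and lower-cased on construction.
    topology : {"linear", "circular"}
        Declared topology.  Metadata only — scanning is always linear.
    """

    id: str
    residues: str
    topology: Topology = "linear"
    length: int = field(init=False)

    def __post_init__(self) -> None:
        norm = normalize_residues(self.residues)
        object.__setattr__(self, "residues", norm)
        object.__setattr__(self, "length", len(norm))

    def __len__(self) -> int:
        return self.length


def normalize_residues(residues: str) -> str:
    """Lower-case, map RNA u->t, and validate against {a,c,g,t,n}."""
    norm = residues.lower().replace("u", "t")
    bad = set(norm) - VALID_CHARS
    if bad:
        raise SequenceError(
            f"invalid nucleotide characters {sorted(bad)!r}; "
            "allowed alphabet is {a,c,g,t,n,u}"
        )
    return norm


def read_sequence(path: Union[str, Path], format: str = "fasta") -> GenomeSequence:
    """Read the first record of a FASTA or GenBank file as a :class:`GenomeSequence`.

    Multi-record files emit a warning and use the first record.  Characters
    outside {a,c,g,t,n,u} (case-insensitive) abort with :class:`SequenceError`.
    """
    path = Path(path)
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format {format!r}; use 'fasta' or 'genbank'")
    if not path.exists():
        raise SequenceError(f"sequence file not found: {path}")
    records = list(SeqIO.parse(str(path), format))
    if not records:
        raise SequenceError(f"no sequence records in {path}")
    if len(records) > 1:
        warnings.warn(
            f"{path} contains {len(records)} records; using the first "
            f"({records[0].id})",
            stacklevel=2,
        )
    rec = records[0]
    if len(rec.seq) == 0:
        raise SequenceError(f"record {rec.id!r} in {path} is empty")
    topology: Topology = "linear"
    if format == "genbank" and rec.annotations.get("topology") == "circular":
        topology = "circular"
    return GenomeSequence(id=rec.id, residues=str(rec.seq), topology=topology)


_COMPLEMENT = str.maketrans("acgtn", "tgcan")


def reverse_complement(residues: str) -> str:
    """Watson–Crick reverse complement over {a,c,g,t,n}; n maps to n."""
    bad = set(residues) - VALID_CHARS
    if bad:
        raise SequenceError(f"invalid nucleotide characters {sorted(bad)!r}")
    return residues.translate(_COMPLEMENT)[::-1]


def write_fasta(
    records: Iterable[tuple[str, str]], handle_or_path: Union[str, Path, TextIO]
) -> None:
    """Write (header, sequence) pairs as FASTA, 70 columns per line."""
    def _write(fh: TextIO) -> None:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    if isinstance(handle_or_path, (str, Path)):
        with open(handle_or_path, "w") as fh:
            _write(fh)
    else:
        _write(handle_or_path)


def roundtrip_check(genome: GenomeSequence) -> bool:
    """True iff writing then re-reading the genome reproduces its residues."""
    import io

    buf = io.StringIO()
    write_fasta([(genome.id, genome.residues)], buf)
    buf.seek(0)
    rec = next(SeqIO.parse(buf, "fasta"))
    return str(rec.seq) == genome.residues
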