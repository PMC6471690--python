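"""Homology triage of candidate ORFs with local BLAST+ executables.

Filtering: every candidate's translated sequence is searched against a known
protein database with ``blastp``.  Two proteins are considered similar when
the alignment bitscore is at least 200 (inclusive).  The candidate set is
partitioned three ways:

* ``to_drop``              — similar to a protein already known in the input
                             organism (excluded from all downstream output);
* ``known_other_organism`` — similar to a protein known in another organism;
* ``no_known_protein``     — no similar known protein (including no hit).

Selection: the ``no_known_protein`` set is screened against an EST
(expressed sequence tag) nucleotide database with ``tblastn`` to look for
transcript evidence.  ``to_drop`` candidates are never re-queried.

"Input organism" matching is by taxon id when the hit carries one and a
``self_taxid`` is configured, otherwise by case-insensitive scientific-name
prefix (``self_name``), so the operator controls how narrow "same organism"
is (species vs cultivar group).

Executable and database locations come from a ``data.properties``-style
key=value config file (keys: ``blastp_path``, ``tblastn_path``,
``protein_db``, ``est_db``, ``self_taxid``, ``self_name``).
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Literal, Optional, Sequence, Tuple, Union

from .classifier import OrfLabel
from .scanner import OrfCandidate
from .sequence_io import write_fasta

SIMILARITY_THRESHOLD = 200.0  # bitscore at/above which proteins are "similar"
REPORT_BIN_EDGE = 80.0        # lower edge of the secondary evidence bin

Program = Literal["blastp", "tblastn"]
Partition = Literal["to_drop", "known_other_organism", "no_known_protein"]
BitscoreBin = Literal["ge200", "80to200", "below80", "none"]

# outfmt 6 with explicit columns; staxids/stitle let us recover taxonomy and
# the bracketed [Organism] of NCBI-style deflines without a taxdb install.
_OUTFMT = "6 qseqid sseqid bitscore staxids stitle"


class ConfigError(RuntimeError):
    """A required executable or database path is missing or wrong."""


class BlastError(RuntimeError):
    """The aligner exited nonzero; carries its stderr."""


@dataclass(frozen=True)
class BlastHitSummary:
    """Best hit for one query; absent hits are represented by no summary."""

    query_id: str
    best_bitscore: float
    best_hit_accession: str
    program: Program
    best_hit_organism: Optional[str] = None
    best_hit_taxid: Optional[str] = None


@dataclass
class TriageConfig:
    blastp_path: str = "blastp"
    tblastn_path: str = "tblastn"
    protein_db: Optional[str] = None
    est_db: Optional[str] = None
    self_taxid: Optional[str] = None
    self_name: Optional[str] = None


def load_config(path: Union[str, Path]) -> TriageConfig:
    """Parse a key=value properties file into a :class:`TriageConfig`."""
    cfg = TriageConfig()
    known = set(vars(cfg))
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in known:
            setattr(cfg, key, value or None)
    return cfg


def _require(path: Optional[str], key: str, executable: bool = False) -> str:
    if not path:
        raise ConfigError(f"config key {key!r} is not set")
    if executable:
        resolved = shutil.which(path)
        if resolved is None:
            raise ConfigError(f"config key {key!r}: executable not found: {path}")
        return resolved
    # BLAST dbs are a basename plus index files (.pin/.nin etc.)
    base = Path(path)
    if not any(base.parent.glob(base.name + ".*")) and not base.exists():
        raise ConfigError(f"config key {key!r}: database not found: {path}")
    return path


def _parse_organism(stitle: str) -> Optional[str]:
    """Extract the bracketed [Organism] of an NCBI-style defline, if any."""
    lo, hi = stitle.rfind("["), stitle.rfind("]")
    if 0 <= lo < hi:
        return stitle[lo + 1 : hi].strip() or None
    return None


def _run_blast(
    program: Program,
    executable: str,
    db: str,
    queries: Sequence[Tuple[str, str]],
    extra_args: Sequence[str] = (),
) -> List[BlastHitSummary]:
    """Run one batch search and return the best-bitscore hit per query."""
    if not queries:
        raise ValueError("no candidates to search")
    with tempfile.NamedTemporaryFile("w", suffix=".faa", delete=False) as tmp:
        write_fasta(queries, tmp)
        qpath = tmp.name
    try:
        proc = subprocess.run(
            [executable, "-query", qpath, "-db", db, "-outfmt", _OUTFMT, *extra_args],
            capture_output=True,
            text=True,
        )
    finally:
        Path(qpath).unlink(missing_ok=True)
    if proc.returncode != 0:
        raise BlastError(f"{program} failed (exit {proc.returncode}):\n{proc.stderr}")
    best: Dict[str, BlastHitSummary] = {}
    for line in proc.stdout.splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        qseqid, sseqid, bitscore = fields[0], fields[1], float(fields[2])
        staxids = fields[3] if len(fields) > 3 else ""
        stitle = fields[4] if len(fields) > 4 else ""
        prev = best.get(qseqid)
        if prev is None or bitscore > prev.best_bitscore:
            taxid = staxids.split(";")[0].strip() if staxids and staxids != "N/A" else None
            best[qseqid] = BlastHitSummary(
                query_id=qseqid,
                best_bitscore=bitscore,
                best_hit_accession=sseqid,
                program=program,
                best_hit_organism=_parse_organism(stitle),
                best_hit_taxid=taxid if taxid != "0" else None,
            )
    return [best[q] for q, _ in queries if q in best]


def run_protein_search(
    candidates: Sequence[OrfCandidate], config: TriageConfig
) -> List[BlastHitSummary]:
    """blastp of candidate amino-acid sequences vs the known-protein database."""
    db = _require(config.protein_db, "protein_db")
    exe = _require(config.blastp_path, "blastp_path", executable=True)
    return _run_blast("blastp", exe, db, [(c.id, c.aa_seq) for c in candidates])


def run_est_search(
    candidates: Sequence[OrfCandidate], config: TriageConfig
) -> List[BlastHitSummary]:
    """tblastn of candidate amino-acid sequences vs the EST nucleotide database."""
    db = _require(config.est_db, "est_db")
    exe = _require(config.tblastn_path, "tblastn_path", executable=True)
    return _run_blast("tblastn", exe, db, [(c.id, c.aa_seq) for c in candidates])


def is_self_organism(
    hit: BlastHitSummary, self_taxid: Optional[str], self_name: Optional[str]
) -> bool:
    """Does the hit come from the input organism, under the configured rule?"""
    if self_taxid and hit.best_hit_taxid:
        return hit.best_hit_taxid == self_taxid
    if self_name and hit.best_hit_organism:
        return hit.best_hit_organism.lower().startswith(self_name.lower())
    return False


def partition_candidates(
    summaries: Sequence[BlastHitSummary],
    candidates: Sequence[OrfCandidate],
    self_taxid: Optional[str] = None,
    self_name: Optional[str] = None,
    threshold: float = SIMILARITY_THRESHOLD,
) -> Dict[Partition, List[OrfCandidate]]:
    """Three-way partition of candidates by protein-similarity evidence.

    The threshold comparison is inclusive: bitscore == threshold counts as
    similar.  Candidates without any hit fall in ``no_known_protein``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    by_query = {s.query_id: s for s in summaries}
    parts: Dict[Partition, List[OrfCandidate]] = {
        "to_drop": [],
        "known_other_organism": [],
        "no_known_protein": [],
    }
    for cand in candidates:
        hit = by_query.get(cand.id)
        if hit is None or hit.best_bitscore < threshold:
            parts["no_known_protein"].append(cand)
        elif is_self_organism(hit, self_taxid, self_name):
            parts["to_drop"].append(cand)
        else:
            parts["known_other_organism"].append(cand)
    return parts


def bitscore_bin(summary: Optional[BlastHitSummary]) -> BitscoreBin:
    """Reporting bin for a best hit: [200,inf), [80,200), [0,80), or none."""
    if summary is None:
        return "none"
    s = summary.best_bitscore
    if s >= SIMILARITY_THRESHOLD:
        return "ge200"
    if s >= REPORT_BIN_EDGE:
        return "80to200"
    return "below80"


@dataclass
class TriageRecord:
    """A candidate joined with its label and best homology evidence."""

    candidate: OrfCandidate
    label: OrfLabel
    partition: Partition
    protein_hit: Optional[BlastHitSummary] = None
    est_hit: Optional[BlastHitSummary] = None

    @property
    def bitscore_bin(self) -> BitscoreBin:
        return bitscore_bin(self.protein_hit if self.protein_hit else self.est_hit)


def triage(
    candidates: Sequence[OrfCandidate],
    labels: Sequence[OrfLabel],
    config: TriageConfig,
) -> List[TriageRecord]:
    """Run Filtering then Selection; to_drop candidates are dropped.

    Returns one record per retained candidate: the protein-similar set
    (other organisms) with their blastp evidence, and the no-known-protein
    set with tblastn EST evidence where found.
    """
    if len(candidates) != len(labels):
        raise ValueError("candidates and labels must align")
    label_of = {c.id: l for c, l in zip(candidates, labels)}
    summaries = run_protein_search(candidates, config) if candidates else []
    by_query = {s.query_id: s for s in summaries}
    parts = partition_candidates(
        summaries, candidates, self_taxid=config.self_taxid, self_name=config.self_name
    )
    records: List[TriageRecord] = []
    for cand in parts["known_other_organism"]:
        records.append(
            TriageRecord(cand, label_of[cand.id], "known_other_organism", protein_hit=by_query.get(cand.id))
        )
    unknown = parts["no_known_protein"]
    est_by_query: Dict[str, BlastHitSummary] = {}
    if unknown and config.est_db:
        est_by_query = {s.query_id: s for s in run_est_search(unknown, config)}
    for cand in unknown:
        records.append(
            TriageRecord(
                cand,
                label_of[cand.id],
                "no_known_protein",
                protein_hit=by_query.get(cand.id),
                est_hit=est_by_query.get(cand.id),
            )
        )
    return records
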