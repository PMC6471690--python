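"""End-to-end orchestration: extraction -> classification -> triage -> report.

Also hosts the convention-sweep harness used for genome-scale summaries:
because "ORF length" may or may not include the stop codon, and sub/int
overlap may or may not be restricted to the same strand, the sweep reports
candidate/novel counts under all four combinations of those two documented
switches.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Union

from .classifier import StrandMode, classify_all, count_novel
from .report import write_catalogues
from .scanner import DEFAULT_THETA_LEN, CodonModel, OrfCandidate, extract_orfs, standard_orfs
from .sequence_io import GenomeSequence, read_sequence
from .triage import TriageConfig, TriageRecord, triage


@dataclass
class ExtractionSummary:
    """Counts the extraction + classification stages produce on one genome."""

    total_candidates: int
    standard_orf_count: int
    novel_candidates: int  # not identically extractable by a standard scanner
    label_counts: Dict[str, int]

    @property
    def novel_fraction(self) -> float:
        return self.novel_candidates / self.total_candidates if self.total_candidates else 0.0


def summarize_extraction(
    genome: GenomeSequence,
    theta_len: int = DEFAULT_THETA_LEN,
    codon_model: Optional[CodonModel] = None,
    length_includes_stop: bool = False,
    strand_mode: StrandMode = "same",
) -> ExtractionSummary:
    candidates = extract_orfs(
        genome, codon_model, theta_len=theta_len, length_includes_stop=length_includes_stop
    )
    standard = standard_orfs(genome, theta_len=theta_len, length_includes_stop=length_includes_stop)
    labels = classify_all(candidates, standard, strand_mode=strand_mode)
    total, novel = count_novel(candidates, standard)
    return ExtractionSummary(
        total_candidates=total,
        standard_orf_count=len(standard),
        novel_candidates=novel,
        label_counts=dict(Counter(l.value for l in labels)),
    )


def paper_scale_counts(
    genome: GenomeSequence, theta_len: int = DEFAULT_THETA_LEN
) -> Dict[str, ExtractionSummary]:
    """Extraction summaries under the 2x2 grid of open conventions.

    Keys are ``"len_excl|same"``-style: length convention (stop codon
    excluded/included in the theta comparison) x overlap strand rule.
    """
    out: Dict[str, ExtractionSummary] = {}
    for includes, len_tag in ((False, "len_excl"), (True, "len_incl")):
        for mode in ("same", "any"):
            out[f"{len_tag}|{mode}"] = summarize_extraction(
                genome,
                theta_len=theta_len,
                length_includes_stop=includes,
                strand_mode=mode,  # type: ignore[arg-type]
            )
    return out


def run_pipeline(
    genome_path: Union[str, Path],
    out_dir: Union[str, Path],
    config: Optional[TriageConfig] = None,
    format: str = "fasta",
    theta_len: int = DEFAULT_THETA_LEN,
    codon_model: Optional[CodonModel] = None,
    strand_mode: StrandMode = "same",
) -> List[TriageRecord]:
    """Run extraction, classification, BLAST triage and catalogue writing.

    When ``config`` is None (or has no protein database) the BLAST stages are
    skipped and no catalogues are written; the labeled candidates are still
    returned as records with partition ``no_known_protein`` and no evidence.
    """
    genome = read_sequence(genome_path, format=format)
    candidates = extract_orfs(genome, codon_model, theta_len=theta_len)
    standard = standard_orfs(genome, theta_len=theta_len)
    labels = classify_all(candidates, standard, strand_mode=strand_mode)
    if config is None or not config.protein_db:
        return [
            TriageRecord(c, l, "no_known_protein") for c, l in zip(candidates, labels)
        ]
    records = triage(candidates, labels, config)
    write_catalogues(records, out_dir)
    return records
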