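"""Brute-force reference for ORF extraction, independent of the scanner.

Enumerates every codon position in all six frames, pairs each start codon
with its nearest downstream in-frame stop, keeps the earliest start per stop,
and applies the length threshold.  Translation goes through Bio.Seq rather
than the package's codon map.
"""

from bisect import bisect_left
from typing import List, Optional

from Bio.Seq import Seq

from editorf.scanner import CodonModel, OrfCandidate
from editorf.sequence_io import GenomeSequence, reverse_complement


def _translate_ref(nt: str) -> str:
    aa = str(Seq(nt).translate(table=1))
    return ("M" + aa[1:]) if aa else aa


def brute_force_orfs(
    genome: GenomeSequence,
    model: Optional[CodonModel] = None,
    theta_len: int = 300,
    length_includes_stop: bool = False,
) -> List[OrfCandidate]:
    model = model or CodonModel()
    starts_set, stops_set = model.active_starts, model.active_stops
    min_sense = max(3, theta_len - 3 if length_includes_stop else theta_len)
    L = genome.length
    out: List[OrfCandidate] = []
    for strand, residues in (("fwd", genome.residues), ("rev", reverse_complement(genome.residues))):
        for frame in (1, 2, 3):
            positions = range(frame - 1, len(residues) - 2, 3)
            start_idx = [i for i in positions if residues[i : i + 3] in starts_set]
            stop_idx = [i for i in positions if residues[i : i + 3] in stops_set]
            # earliest start whose nearest downstream stop is this stop
            best_start = {}
            for s in start_idx:
                k = bisect_left(stop_idx, s + 3)
                if k == len(stop_idx):
                    continue
                stop = stop_idx[k]
                if stop not in best_start or s < best_start[stop]:
                    best_start[stop] = s
            for stop, s in sorted(best_start.items()):
                if stop - s < min_sense:
                    continue
                nt = residues[s:stop]
                lo, hi = s + 1, stop + 3
                fwd_iv = (lo, hi) if strand == "fwd" else (L - hi + 1, L - lo + 1)
                out.append(
                    OrfCandidate(
                        strand=strand,
                        frame=frame,
                        start_pos=s + 1,
                        stop_pos=stop + 1,
                        start_type=model.start_type(residues[s : s + 3]),
                        stop_type=model.stop_type(residues[stop : stop + 3]),
                        nt_seq=nt,
                        aa_seq=_translate_ref(nt),
                        fwd_interval=fwd_iv,
                    )
                )
    out.sort(key=lambda c: (c.strand, c.frame, c.start_pos))
    return out
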