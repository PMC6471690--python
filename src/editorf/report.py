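"""Final catalogues: one TSV per (search type, bitscore bin).

Four files are written, mirroring the method's result tables:

* ``protein_ge200.tsv``   — blastp evidence, bitscore >= 200
* ``protein_80to200.tsv`` — blastp evidence, bitscore in [80, 200)
* ``est_ge200.tsv``       — tblastn (EST) evidence, bitscore >= 200
* ``est_80to200.tsv``     — tblastn evidence, bitscore in [80, 200)

plus ``unsupported.tsv`` for retained candidates whose best evidence scores
below 80 (or that have none) — kept for transparency rather than dropped
silently.  The 80–200 bin is half-open, [80, 200), so a score of exactly 200
appears only in the >=200 catalogue.  Rows are ordered by descending
bitscore, then ascending start position.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence, Union

import pandas as pd

from .triage import TriageRecord, bitscore_bin

COLUMNS = [
    "seq_nr",
    "orf_id",
    "start_type",
    "stop_type",
    "strand",
    "start_codon_pos",
    "orf_length",
    "orf_type",
    "bitscore",
    "organism",
]


def _rows(records: Sequence[TriageRecord], which: str) -> pd.DataFrame:
    rows: List[dict] = []
    for rec in records:
        hit = rec.protein_hit if which == "protein" else rec.est_hit
        rows.append(
            {
                "orf_id": rec.candidate.id,
                "start_type": rec.candidate.start_type.capitalize(),
                "stop_type": rec.candidate.stop_type.capitalize(),
                "strand": rec.candidate.strand,
                "start_codon_pos": rec.candidate.start_pos,
                "orf_length": rec.candidate.orf_length,
                "orf_type": rec.label.value,
                "bitscore": hit.best_bitscore if hit else None,
                "organism": (hit.best_hit_organism or "") if hit else "",
                "_bin": bitscore_bin(hit),
            }
        )
    df = pd.DataFrame(rows, columns=[c for c in COLUMNS if c != "seq_nr"] + ["_bin"])
    df = df.sort_values(
        ["bitscore", "start_codon_pos"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return df


def _emit(df: pd.DataFrame, path: Path) -> None:
    out = df.drop(columns="_bin").copy()
    out.insert(0, "seq_nr", range(1, len(out) + 1))
    out.to_csv(path, sep="\t", index=False)


def write_catalogues(
    records: Sequence[TriageRecord], out_dir: Union[str, Path]
) -> Dict[str, Path]:
    """Write the four binned catalogues (+ unsupported) and return their paths."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cannot write to output directory {out_dir}: {exc}") from exc

    protein_records = [r for r in records if r.partition == "known_other_organism"]
    est_records = [r for r in records if r.partition == "no_known_protein"]

    paths: Dict[str, Path] = {}
    leftovers: List[pd.DataFrame] = []
    for which, subset in (("protein", protein_records), ("est", est_records)):
        df = _rows(subset, which)
        for bin_name in ("ge200", "80to200"):
            path = out_dir / f"{which}_{bin_name}.tsv"
            _emit(df[df["_bin"] == bin_name], path)
            paths[f"{which}_{bin_name}"] = path
        leftovers.append(df[df["_bin"].isin(["below80", "none"])])
    unsupported = out_dir / "unsupported.tsv"
    _emit(pd.concat(leftovers, ignore_index=True) if leftovers else _rows([], "protein"), unsupported)
    paths["unsupported"] = unsupported
    return paths
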