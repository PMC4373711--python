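"""Library curation: resolution and sequence-identity redundancy filters.

Reference libraries for a statistical potential must not over-represent any
one protein family, so candidate entries are filtered to a maximum pairwise
sequence identity; crystallographic quality is controlled by a resolution
cutoff.  Identity is computed from one global alignment (BLOSUM62, gap open
11, extend 1) as identical columns / alignment length.

Redundancy removal is greedy: entries are visited best-resolution first
(NMR entries last, entry id as the final tiebreak) and an entry is kept iff
its identity to every already-kept entry is below the cutoff, so the
retained set is mutually non-redundant and high-resolution structures win
conflicts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import InputError


@dataclass(frozen=True)
class LibraryEntry:
    """One candidate structure for a reference library."""

    entry_id: str  # e.g. "1NA0:A"
    sequence: str  # one-letter amino acids, X allowed
    resolution: Optional[float] = None  # Å; None for NMR/model entries
    source_path: Optional[str] = None
    method: str = ""  # e.g. "xray", "nmr"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"entry {self.entry_id}: empty sequence")
        if self.resolution is not None and self.resolution <= 0:
            raise InputError(f"entry {self.entry_id}: nonpositive resolution")

    @property
    def is_nmr(self) -> bool:
        return self.resolution is None or self.method.lower() == "nmr"


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(s1: str, s2: str) -> float:
    """Fractional sequence identity from one global alignment.

    Identity = identical aligned residue pairs / alignment length (gaps
    included in the denominator).  ``X`` never counts as a match.
    """
    if not s1 or not s2:
        raise InputError("cannot align an empty sequence")
    alignment = _ALIGNER.align(s1, s2)[0]
    row1, row2 = alignment[0], alignment[1]
    matches = sum(
        1 for c1, c2 in zip(row1, row2) if c1 == c2 and c1 not in ("-", "X")
    )
    return matches / len(row1)


def filter_resolution(
    entries: Iterable[LibraryEntry],
    max_resolution: float,
    keep_nmr: bool = False,
) -> list[LibraryEntry]:
    """Keep entries with resolution <= cutoff; NMR entries iff ``keep_nmr``."""
    kept = []
    for e in entries:
        if e.resolution is None:
            if keep_nmr:
                kept.append(e)
        elif e.resolution <= max_resolution:
            kept.append(e)
    return kept


def _selection_key(e: LibraryEntry) -> tuple:
    # resolution ascending, NMR (no resolution) after everything, id tiebreak
    return (e.is_nmr, e.resolution if e.resolution is not None else float("inf"), e.entry_id)


def filter_redundancy(
    entries: Sequence[LibraryEntry],
    identity_cutoff: float,
    return_log: bool = False,
):
    """Greedy non-redundant subset at the given pairwise identity cutoff.

    Returns the retained entries (in selection order); with
    ``return_log=True`` also a list of (rejected_id, reason, conflicting_id)
    tuples.
    """
    if not 0 < identity_cutoff <= 1:
        raise InputError("identity cutoff must be in (0, 1]")
    retained: list[LibraryEntry] = []
    log: list[tuple[str, str, str]] = []
    for e in sorted(entries, key=_selection_key):
        conflict = None
        for kept in retained:
            if pairwise_identity(e.sequence, kept.sequence) >= identity_cutoff:
                conflict = kept
                break
        if conflict is None:
            retained.append(e)
        else:
            log.append(
                (e.entry_id, f"identity >= {identity_cutoff:g}", conflict.entry_id)
            )
    if return_log:
        return retained, log
    return retained


# ---------------------------------------------------------------------------
# manifest I/O

MANIFEST_COLUMNS = ["entry_id", "path", "chain", "resolution", "method"]


def read_manifest(path) -> list[dict]:
    """Read a TSV manifest (entry_id, path, chain, resolution, method).

    ``resolution`` may be empty or ``NA`` for NMR/model entries.  Relative
    structure paths are resolved against the manifest's directory.
    """
    base = Path(path).parent
    rows: list[dict] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "entry_id" not in reader.fieldnames:
            raise InputError(f"manifest {path} lacks an entry_id column")
        for rec in reader:
            res_text = (rec.get("resolution") or "").strip()
            resolution = None if res_text in ("", "NA", "-") else float(res_text)
            p = Path(rec["path"])
            if not p.is_absolute():
                p = base / p
            rows.append(
                {
                    "entry_id": rec["entry_id"],
                    "path": str(p),
                    "chain": (rec.get("chain") or "").strip(),
                    "resolution": resolution,
                    "method": (rec.get("method") or "").strip(),
                }
            )
    return rows


def write_manifest(rows: Sequence[dict], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MANIFEST_COLUMNS)
        for r in rows:
            res = r.get("resolution")
            writer.writerow(
                [
                    r["entry_id"],
                    r.get("path", ""),
                    r.get("chain", ""),
                    "" if res is None else f"{res:g}",
                    r.get("method", ""),
                ]
            )
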