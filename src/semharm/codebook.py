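"""Codebook ingestion and case-insensitive identifier harmonisation.

Longitudinal cohort studies re-release the same variable across waves,
often with identifiers that differ only in letter case.  Treating such
identifiers as the same variable is the first, purely lexical, step of
harmonisation; the semantic steps (search, clustering) operate on the
deduplicated codebook.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Key under which records lacking a wave are counted.
UNASSIGNED_WAVE = "unassigned"


@dataclass(frozen=True)
class VariableRecord:
    """One variable of a data dictionary.

    ``degenerate`` flags records whose description was empty in the
    source file; such records are carried through bookkeeping but are
    not meaningfully embeddable.
    """

    identifier: str
    description: str
    wave: int | None = None
    source: str | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.identifier or not self.identifier.strip():
            raise ValueError("identifier must be non-empty")
        if self.identifier != self.identifier.strip():
            object.__setattr__(self, "identifier", self.identifier.strip())
        if self.description != self.description.strip():
            object.__setattr__(self, "description", self.description.strip())
        if not self.description and not self.degenerate:
            raise ValueError(
                f"record {self.identifier!r}: empty description requires the "
                "degenerate flag"
            )
        if self.wave is not None and self.wave < 1:
            raise ValueError(f"record {self.identifier!r}: wave must be >= 1")


@dataclass(frozen=True)
class Codebook:
    """Ordered collection of variable records, as read from file."""

    records: tuple[VariableRecord, ...]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    @property
    def identifiers(self) -> tuple[str, ...]:
        return tuple(r.identifier for r in self.records)

    @property
    def descriptions(self) -> tuple[str, ...]:
        return tuple(r.description for r in self.records)


@dataclass(frozen=True)
class HarmonisedCodebook:
    """Codebook after case-insensitive identifier deduplication.

    ``merge_map`` maps each canonical identifier (the first occurrence's
    spelling) to every source record it absorbed, so no input record is
    lost by the merge.
    """

    unique_records: tuple[VariableRecord, ...]
    merge_map: Mapping[str, tuple[VariableRecord, ...]]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.unique_records)

    @property
    def identifiers(self) -> tuple[str, ...]:
        return tuple(r.identifier for r in self.unique_records)

    @property
    def descriptions(self) -> tuple[str, ...]:
        return tuple(r.description for r in self.unique_records)

    def to_codebook(self) -> Codebook:
        return Codebook(records=self.unique_records, provenance=self.provenance)


def _detect_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_codebook(
    path: str | Path,
    *,
    delimiter: str | None = None,
    identifier_col: str = "variable",
    description_col: str = "description",
    wave_col: str = "wave",
    source_col: str = "source",
) -> Codebook:
    """Read a CSV/TSV data dictionary into a :class:`Codebook`.

    The delimiter defaults to tab for ``.tsv``/``.tab`` files and comma
    otherwise.  A header row is required; ``wave`` and ``source`` columns
    are optional.  Row order is preserved exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"codebook file not found: {path}")
    sep = delimiter if delimiter is not None else _detect_delimiter(path)

    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh, delimiter=sep), None)
    if not header:
        raise ValueError(f"codebook file {path} is empty (header required)")
    dupes = {c for c in header if header.count(c) > 1}
    if dupes:
        raise ValueError(
            f"codebook file {path} has duplicate column name(s): {sorted(dupes)}"
        )
    for col in (identifier_col, description_col):
        if col not in header:
            raise ValueError(f"codebook file {path} lacks column {col!r}")

    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    records: list[VariableRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        ident = row_d[identifier_col].strip()
        desc = row_d[description_col].strip()
        wave: int | None = None
        if wave_col in df.columns:
            raw = row_d[wave_col].strip()
            if raw:
                try:
                    wave = int(raw)
                except ValueError as exc:
                    raise ValueError(
                        f"row {idx}: wave value {raw!r} is not an integer"
                    ) from exc
        source = row_d[source_col].strip() or None if source_col in df.columns else None
        degenerate = not desc
        if degenerate:
            logger.warning("row %d (%s): empty description, flagged degenerate",
                           idx, ident)
        records.append(VariableRecord(ident, desc, wave, source, degenerate))
    return Codebook(records=tuple(records), provenance=str(path))


def harmonise_identifiers(cb: Codebook | HarmonisedCodebook) -> HarmonisedCodebook:
    """Merge records whose identifiers match after Unicode casefolding.

    The canonical record for each group is the first occurrence in input
    order; every input record is retained in exactly one merge group.
    Idempotent: harmonising an already-harmonised codebook is a no-op.
    """
    records = cb.unique_records if isinstance(cb, HarmonisedCodebook) else cb.records
    groups: dict[str, list[VariableRecord]] = {}
    canonical: dict[str, VariableRecord] = {}
    order: list[str] = []
    for rec in records:
        key = rec.identifier.casefold()
        if key not in groups:
            groups[key] = []
            canonical[key] = rec
            order.append(key)
        groups[key].append(rec)
    return HarmonisedCodebook(
        unique_records=tuple(canonical[k] for k in order),
        merge_map={canonical[k].identifier: tuple(groups[k]) for k in order},
        provenance=cb.provenance,
    )


def count_by_wave(cb: Codebook | HarmonisedCodebook) -> dict[int | str, int]:
    """Count records per wave; records without a wave fall under
    :data:`UNASSIGNED_WAVE`."""
    records = cb.unique_records if isinstance(cb, HarmonisedCodebook) else cb.records
    counts: dict[int | str, int] = {}
    for rec in records:
        key: int | str = rec.wave if rec.wave is not None else UNASSIGNED_WAVE
        counts[key] = counts.get(key, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (isinstance(kv[0], str), kv[0])))


def write_harmonised(hcb: HarmonisedCodebook, tsv_path: str | Path,
                     merge_map_path: str | Path | None = None) -> None:
    """Write unique records as TSV and (optionally) the merge map as JSON."""
    rows = [
        {
            "variable": r.identifier,
            "description": r.description,
            "wave": "" if r.wave is None else r.wave,
            "source": r.source or "",
        }
        for r in hcb.unique_records
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if merge_map_path is not None:
        payload = {
            canon: [
                {"identifier": m.identifier,
                 "wave": m.wave, "source": m.source}
                for m in merged
            ]
            for canon, merged in hcb.merge_map.items()
        }
        with open(merge_map_path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
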