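"""Readers and writers for the tabular interchange formats of the pipeline.

The pipeline consumes a simplified two-file Darwin-Core-style archive
(an occurrence table plus a multimedia table, both tab-separated text with a
header row), an authoritative species checklist, and emits/consumes run
manifests as versioned JSON.  Full Darwin Core Archive packaging (zip,
meta.xml, EML) is deliberately out of scope: the two TSV tables carry all
the information the analysis needs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: taxonomic ranks interpreted by the pipeline, coarsest first
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: ranks that must be present for a record to be usable
REQUIRED_RANKS = ("kingdom", "class", "order", "species")

#: occurrence-table columns (``scientificName`` doubles as the species rank)
OCCURRENCE_COLUMNS = ("id", "scientificName", "kingdom", "phylum", "class",
                      "order", "family", "genus")
MULTIMEDIA_COLUMNS = ("coreid", "identifier")
CHECKLIST_COLUMNS = ("taxon", "rank", "species_count")

MANIFEST_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """A table or manifest violates the expected schema."""


@dataclass(frozen=True)
class ObservationRecord:
    """One citizen-science occurrence: a species sighting with 0+ images."""

    observation_id: str
    species: str
    taxonomy: Mapping[str, str]
    image_refs: tuple[str, ...] = ()

    @property
    def has_image(self) -> bool:
        return len(self.image_refs) > 0


@dataclass(frozen=True)
class ChecklistEntry:
    """Accepted species richness for one taxon at one rank."""

    taxon: str
    rank: str
    accepted_species_count: int


@dataclass
class OccurrenceSet:
    """Parsed occurrence records plus a tally of skipped malformed rows.

    Iterable and sized, so most call sites can treat it as a plain list of
    :class:`ObservationRecord`.
    """

    records: list[ObservationRecord] = field(default_factory=list)
    n_skipped: int = 0

    def __iter__(self) -> Iterator[ObservationRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def read_occurrences(occurrence_path: str | Path,
                     multimedia_path: str | Path | None = None,
                     ) -> OccurrenceSet:
    """Read occurrence and (optional) multimedia tables into records.

    Image references are joined onto occurrences via the multimedia table's
    ``coreid`` column.  Rows whose taxonomy cannot be interpreted (an empty
    kingdom, class, order or scientificName) are skipped and counted, never
    silently dropped.

    Raises
    ------
    FormatError
        if a required column is absent or an occurrence id is duplicated.
    """
    occ = _read_tsv(occurrence_path, ("id", "scientificName"))
    rank_cols = [c for c in RANKS[:-1] if c in occ.columns]
    if any(r not in occ.columns for r in ("kingdom", "class", "order")):
        raise FormatError(
            f"{occurrence_path}: occurrence table needs kingdom, class and "
            "order columns")

    dupes = occ["id"][occ["id"].duplicated()].unique()
    if len(dupes):
        raise FormatError(
            f"duplicate observation id(s): {', '.join(map(str, dupes[:5]))}")

    media: dict[str, list[str]] = {}
    if multimedia_path is not None:
        mm = _read_tsv(multimedia_path, MULTIMEDIA_COLUMNS)
        for coreid, ident in zip(mm["coreid"], mm["identifier"]):
            media.setdefault(str(coreid), []).append(str(ident))
        # sorted multiset: the join must not depend on multimedia row order
        for refs in media.values():
            refs.sort()

    out = OccurrenceSet()
    for rowd in occ.to_dict("records"):  # itertuples mangles 'class'
        species = rowd["scientificName"].strip()
        taxonomy = {r: rowd[r].strip() for r in rank_cols if rowd[r].strip()}
        taxonomy["species"] = species
        if not species or any(r not in taxonomy for r in REQUIRED_RANKS):
            out.n_skipped += 1
            continue
        oid = str(rowd["id"])
        out.records.append(ObservationRecord(
            observation_id=oid,
            species=species,
            taxonomy=taxonomy,
            image_refs=tuple(media.get(oid, ())),
        ))
    if out.n_skipped:
        logger.warning("skipped %d occurrence row(s) with unparseable "
                       "taxonomy", out.n_skipped)
    return out


def write_occurrences(records: Iterable[ObservationRecord],
                      occurrence_path: str | Path,
                      multimedia_path: str | Path) -> None:
    """Write records as the two-table archive ``read_occurrences`` reads."""
    occ_rows, mm_rows = [], []
    for rec in records:
        row = {"id": rec.observation_id, "scientificName": rec.species}
        for r in RANKS[:-1]:
            row[r] = rec.taxonomy.get(r, "")
        occ_rows.append(row)
        for ref in rec.image_refs:
            mm_rows.append({"coreid": rec.observation_id, "identifier": ref})
    pd.DataFrame(occ_rows, columns=OCCURRENCE_COLUMNS).to_csv(
        occurrence_path, sep="\t", index=False)
    pd.DataFrame(mm_rows, columns=MULTIMEDIA_COLUMNS).to_csv(
        multimedia_path, sep="\t", index=False)


def read_checklist(path: str | Path) -> list[ChecklistEntry]:
    """Read a species checklist (taxon, rank, species_count) TSV."""
    df = _read_tsv(path, CHECKLIST_COLUMNS)
    seen: set[tuple[str, str]] = set()
    entries = []
    for row in df.itertuples(index=False):
        key = (row.taxon, row.rank)
        if key in seen:
            raise FormatError(f"duplicate checklist entry for {key}")
        seen.add(key)
        try:
            count = int(row.species_count)
        except ValueError:
            raise FormatError(
                f"non-integer species_count {row.species_count!r} "
                f"for taxon {row.taxon!r}") from None
        if count < 0:
            raise FormatError(
                f"negative species_count for taxon {row.taxon!r}")
        entries.append(ChecklistEntry(row.taxon, row.rank, count))
    return entries


def write_checklist(entries: Iterable[ChecklistEntry],
                    path: str | Path) -> None:
    pd.DataFrame(
        [(e.taxon, e.rank, e.accepted_species_count) for e in entries],
        columns=CHECKLIST_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def checklist_counts(entries: Iterable[ChecklistEntry],
                     rank: str) -> dict[str, int]:
    """Map taxon -> accepted species count for one rank."""
    return {e.taxon: e.accepted_species_count
            for e in entries if e.rank == rank}


# ---------------------------------------------------------------------------
# run manifests

def write_manifest(manifest, path: str | Path) -> None:
    """Serialize a RunManifest as versioned JSON (round-trip exact)."""
    payload = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "taxon": manifest.taxon,
        "run_index": manifest.run_index,
        "species": list(manifest.species),
        "seed_species": manifest.seed_species,
        "seed_split": manifest.seed_split,
        "test": {sp: list(ids) for sp, ids in sorted(manifest.test.items())},
        "tasks": [
            {
                "size": task.size,
                "train": {sp: list(ids)
                          for sp, ids in sorted(task.train.items())},
                "validation": {sp: list(ids)
                               for sp, ids in sorted(task.validation.items())},
            }
            for task in manifest.tasks
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_manifest(path: str | Path,
                  known_ids: set[str] | None = None):
    """Read a RunManifest written by :func:`write_manifest`.

    Parameters
    ----------
    known_ids
        If given, every observation id in the manifest must be a member;
        a stale or hand-edited id raises :class:`FormatError`.
    """
    from .run_generation import RunManifest, TaskSplit  # avoid import cycle

    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version != MANIFEST_SCHEMA_VERSION:
        raise FormatError(
            f"{path}: manifest schema version {version!r}, "
            f"expected {MANIFEST_SCHEMA_VERSION}")
    test = {sp: list(ids) for sp, ids in payload["test"].items()}
    tasks = [
        TaskSplit(size=t["size"],
                  train={sp: list(ids) for sp, ids in t["train"].items()},
                  validation={sp: list(ids)
                              for sp, ids in t["validation"].items()},
                  test=test)
        for t in payload["tasks"]
    ]
    manifest = RunManifest(
        taxon=payload["taxon"],
        run_index=payload["run_index"],
        species=list(payload["species"]),
        seed_species=payload["seed_species"],
        seed_split=payload["seed_split"],
        test=test,
        tasks=tasks,
    )
    if known_ids is not None:
        referenced = set()
        for sp_ids in test.values():
            referenced.update(sp_ids)
        for task in tasks:
            for split in (task.train, task.validation):
                for sp_ids in split.values():
                    referenced.update(sp_ids)
        unknown = referenced - known_ids
        if unknown:
            sample = ", ".join(sorted(unknown)[:5])
            raise FormatError(
                f"{path}: manifest references {len(unknown)} unknown "
                f"observation id(s), e.g. {sample}")
    return manifest
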