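"""Consensus taxonomy for metabarcoding ASVs and community-table counts.

Each amplicon sequence variant (ASV) arrives with a read count and a set of
candidate taxon hits with percent identities.  The consensus procedure is:

1. drop low-confidence ASVs (< 8 total reads);
2. keep only hits at the maximum percent identity for the ASV;
3. replace any hit absent from the user-supplied plausible-species list with
   its closest plausible relative — the plausible taxon sharing the deepest
   rank-path prefix, ties broken alphabetically (and reported);
4. a single surviving candidate is assigned at species rank; several
   candidates collapse to their lowest common taxon in the supplied
   taxonomy;
5. taxa flagged as non-estuarine (marine) on the plausible list are valid
   assignments but from an exogenous DNA source (e.g. transported in bird
   feces) and are flagged as such.

The module also implements the count filters applied to the published
community table (which fishes were detected by eDNA vs. seine, at which
rank, and which were new reports for the system).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._fixtures import packaged_data_path

__all__ = [
    "ASVHit",
    "ASVRecord",
    "PlausibleList",
    "ConsensusAssignment",
    "CommunityTable",
    "MIN_READS",
    "filter_asvs",
    "consensus_assign",
    "count_species",
    "load_asv_table",
    "load_plausible_list",
    "load_community_table",
]

#: ASVs with fewer total reads than this are removed (low confidence).
MIN_READS = 8

RANKS = ("class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class ASVHit:
    """One candidate taxon for an ASV with its percent identity."""

    taxon: str
    percent_identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent identity must be in [0, 100], got {self.percent_identity}"
            )


@dataclass(frozen=True)
class ASVRecord:
    """An ASV: identifier, total read count, and candidate taxon hits."""

    asv_id: str
    total_reads: int
    hits: tuple[ASVHit, ...] = ()

    def __post_init__(self) -> None:
        if self.total_reads < 0:
            raise ValueError(f"total_reads must be >= 0, got {self.total_reads}")
        object.__setattr__(self, "hits", tuple(self.hits))


@dataclass(frozen=True)
class ConsensusAssignment:
    """Consensus taxon for one ASV; ``consensus_taxon`` is None if unassigned."""

    asv_id: str
    consensus_taxon: str | None
    rank: str | None
    exogenous: bool = False
    reassigned_from: tuple[str, ...] = ()
    reads: int = 0

    @property
    def unassigned(self) -> bool:
        return self.consensus_taxon is None


class PlausibleList:
    """A reference taxonomy with a plausible-species flag and habitat flags.

    Built from a table with columns ``taxon``, the rank path
    (class, order, family, genus, species), a boolean ``plausible`` column
    (absent means every row is plausible), ``habitat``
    (estuarine/freshwater/marine), ``previously_reported_refs`` and
    ``sequenced``.  Rows with ``plausible=False`` carry lineages for taxa
    that may appear as hits but are not locally credible.
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if "taxon" not in table.columns:
            raise ValueError("plausible list needs a 'taxon' column")
        if "plausible" not in table.columns:
            table["plausible"] = True
        else:
            table["plausible"] = table["plausible"].map(_as_bool)
        self.table = table.set_index("taxon", drop=False)
        self._paths: dict[str, tuple[str, ...]] = {}
        for taxon, row in self.table.iterrows():
            path = tuple(
                str(row[r]) for r in RANKS
                if r in table.columns and str(row.get(r, "")).strip() not in ("", "nan")
            )
            self._paths[taxon] = path
            # internal consistency: a species' own name terminates its path
            if "species" in table.columns and str(row.get("species", "")).strip() not in ("", "nan"):
                if path[-1] != taxon:
                    raise ValueError(
                        f"rank path for {taxon!r} ends at {path[-1]!r}, not itself"
                    )

    # -- lookups -----------------------------------------------------------
    def __contains__(self, taxon: str) -> bool:
        return taxon in self._paths

    def is_plausible(self, taxon: str) -> bool:
        return taxon in self.table.index and bool(self.table.loc[taxon, "plausible"])

    def rank_path(self, taxon: str) -> tuple[str, ...]:
        return self._paths[taxon]

    def is_exogenous(self, taxon: str) -> bool:
        if "habitat" not in self.table.columns or taxon not in self.table.index:
            return False
        return str(self.table.loc[taxon, "habitat"]).strip().lower() == "marine"

    @property
    def plausible_taxa(self) -> list[str]:
        return sorted(self.table.index[self.table["plausible"]])

    def closest_plausible_relative(self, taxon: str) -> str | None:
        """Plausible taxon sharing the deepest rank-path prefix; ties alphabetical."""
        if taxon not in self._paths:
            return None
        path = self._paths[taxon]
        best_depth, best = -1, None
        for candidate in self.plausible_taxa:  # sorted, so ties resolve alphabetically
            if candidate == taxon:
                continue
            depth = _shared_depth(path, self._paths[candidate])
            if depth > best_depth:
                best_depth, best = depth, candidate
        return best if best_depth > 0 else None


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("true", "1", "yes")


def _shared_depth(a: Sequence[str], b: Sequence[str]) -> int:
    depth = 0
    for x, y in zip(a, b):
        if x != y:
            break
        depth += 1
    return depth


def filter_asvs(records: Iterable[ASVRecord]) -> list[ASVRecord]:
    """Retain exactly the ASVs with at least MIN_READS total reads."""
    return [r for r in records if r.total_reads >= MIN_READS]


def consensus_assign(record: ASVRecord, plausible: PlausibleList) -> ConsensusAssignment:
    """Assign one ASV to its consensus taxon under the plausibility rules.

    Candidates with no resolvable plausible relative yield an unassigned
    outcome (``consensus_taxon=None``) rather than being dropped silently.
    """
    if not record.hits:
        return ConsensusAssignment(record.asv_id, None, None, reads=record.total_reads)

    top = max(h.percent_identity for h in record.hits)
    survivors = [h.taxon for h in record.hits if h.percent_identity == top]

    resolved: list[str] = []
    reassigned: list[str] = []
    for taxon in survivors:
        if plausible.is_plausible(taxon):
            resolved.append(taxon)
        else:
            relative = plausible.closest_plausible_relative(taxon)
            if relative is None:
                return ConsensusAssignment(
                    record.asv_id, None, None, reads=record.total_reads
                )
            resolved.append(relative)
            reassigned.append(taxon)

    candidates = sorted(set(resolved))
    if len(candidates) == 1:
        taxon = candidates[0]
        path = plausible.rank_path(taxon)
        rank = RANKS[len(path) - 1] if len(path) <= len(RANKS) else "species"
        return ConsensusAssignment(
            record.asv_id,
            taxon,
            rank,
            exogenous=plausible.is_exogenous(taxon),
            reassigned_from=tuple(reassigned),
            reads=record.total_reads,
        )

    paths = [plausible.rank_path(t) for t in candidates]
    depth = min(_shared_depth(paths[0], p) for p in paths[1:])
    if depth == 0:
        return ConsensusAssignment(record.asv_id, None, None, reads=record.total_reads)
    return ConsensusAssignment(
        record.asv_id,
        paths[0][depth - 1],
        RANKS[depth - 1],
        exogenous=all(plausible.is_exogenous(t) for t in candidates),
        reassigned_from=tuple(reassigned),
        reads=record.total_reads,
    )


# ---------------------------------------------------------------------------
# Community table and count filters


class CommunityTable:
    """Per-taxon detection table: previous references, eDNA reads, seine counts.

    Cell semantics follow the packaged fixture: eDNA reads may be a count,
    0 (not detected), "?" (unknown — possibly subsumed in an ambiguous
    higher-rank ASV; never counted) or blank; seine counts may be a count,
    "Visual" (seen but not captured; excluded from seine counts) or blank.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"taxon", "previous_references", "edna_reads", "seine_count"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"community table missing columns: {sorted(missing)}")
        frame = frame.copy()
        if "rank" not in frame.columns:
            frame["rank"] = "species"
        if "exogenous" not in frame.columns:
            frame["exogenous"] = False
        frame["exogenous"] = frame["exogenous"].map(_as_bool)
        frame["edna_reads_n"] = [
            self._parse_count(row.taxon, "edna_reads", row.edna_reads, unknown="?")
            for row in frame.itertuples()
        ]
        frame["seine_count_n"] = [
            self._parse_count(row.taxon, "seine_count", row.seine_count, unknown="Visual")
            for row in frame.itertuples()
        ]
        self.frame = frame

    @staticmethod
    def _parse_count(taxon: str, column: str, cell, unknown: str) -> float | None:
        text = "" if cell is None else str(cell).strip()
        if text in ("", "nan"):
            return 0.0
        if text == unknown:
            return None  # unknown / non-count marker: excluded from counts
        try:
            return float(text.replace(",", ""))
        except ValueError:
            raise ValueError(
                f"malformed {column} cell {cell!r} in row {taxon!r}"
            ) from None

    def count(self, mode: str) -> int:
        f = self.frame
        edna_pos = f["edna_reads_n"].map(lambda x: x is not None and x > 0)
        seine_pos = f["seine_count_n"].map(lambda x: x is not None and x > 0)
        species_rank = f["rank"] == "species"
        native = ~f["exogenous"]
        new_report = f["previous_references"].astype(str).str.strip().isin(["", "nan"])
        if mode == "edna_all":
            keep = edna_pos
        elif mode == "edna_species_rank":
            keep = edna_pos & species_rank & native
        elif mode == "seine":
            keep = seine_pos
        elif mode == "edna_new_reports":
            keep = edna_pos & species_rank & native & new_report
        elif mode == "seine_new_reports":
            keep = seine_pos & species_rank & native & new_report
        else:
            raise ValueError(f"unknown count mode {mode!r}")
        return int(keep.sum())


def count_species(table: CommunityTable, mode: str) -> int:
    """Species count under one of the published filter modes.

    Modes: ``edna_all`` (taxa with positive eDNA reads, ambiguous-rank and
    exogenous rows included), ``edna_species_rank`` (species-rank,
    non-exogenous eDNA detections), ``seine`` (captured in seines; visual
    sightings excluded), ``edna_new_reports`` / ``seine_new_reports``
    (the corresponding detections with no previous published account).
    """
    return table.count(mode)


# ---------------------------------------------------------------------------
# I/O


def load_asv_table(path: str | Path) -> list[ASVRecord]:
    """Read a long-format ASV TSV: asv_id, total_reads, hit_taxon, percent_identity."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for asv_id, group in frame.groupby("asv_id", sort=False):
        reads = int(group["total_reads"].iloc[0])
        hits = tuple(
            ASVHit(taxon=str(row.hit_taxon), percent_identity=float(row.percent_identity))
            for row in group.itertuples()
        )
        records.append(ASVRecord(asv_id=str(asv_id), total_reads=reads, hits=hits))
    return records


def load_plausible_list(path: str | Path | None = None) -> PlausibleList:
    """Read a plausible-list CSV; default is the packaged estuarine-fish fixture."""
    if path is None:
        path = packaged_data_path("taxonomy.csv")
    frame = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    return PlausibleList(frame)


def load_community_table(path: str | Path | None = None) -> CommunityTable:
    """Read a community-table CSV; default is the packaged published table."""
    if path is None:
        path = packaged_data_path("table2.csv")
    frame = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    return CommunityTable(frame)
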