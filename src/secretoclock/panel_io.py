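"""Data model and I/O for aptamer panels, RFU matrices, sample metadata and gene sets.

The interchange layout is a plain delimited table ("ADAT-lite"): one row per
sample, metadata columns first, then one column per aptamer holding relative
fluorescence units (RFU) either raw-scale or already log2-transformed. Panel
annotation and gene sets travel in their own files (TSV and GMT respectively).

Also implements the panel filtering rules applied before any analysis:
aptamers without an assigned gene symbol are dropped, and when a gene symbol
is measured by exactly one human-target and one mouse-target aptamer the
mouse-specific aptamer is kept and the human one discarded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

SPECIES_VALUES = ("human", "mouse", "unknown")

PANEL_COLUMNS = ["aptamer_id", "gene_symbol", "uniprot_id", "species_target"]
METADATA_COLUMNS = ["sample_id", "genotype", "model", "sex", "cohort", "age_months"]

GENOTYPE_VALUES = ("wildtype", "progeroid")
MODEL_VALUES = ("LmnaG609G", "Zmpste24KO", "reference", "none")
SEX_VALUES = ("male", "female")


class PanelError(ValueError):
    """Raised when a panel, matrix or metadata invariant is violated."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AptamerPanel:
    """Annotation of each aptamer reagent on the assay.

    ``table`` has columns aptamer_id, gene_symbol (may be empty, may be a
    compound "A|B" symbol), uniprot_id and species_target. Aptamer ids are
    unique; compound symbols contain no empty components.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.table.columns]
        if missing:
            raise PanelError(f"panel table missing columns: {missing}")
        self.table = self.table[PANEL_COLUMNS].reset_index(drop=True).copy()
        for col in PANEL_COLUMNS:
            self.table[col] = self.table[col].fillna("").astype(str)
        ids = self.table["aptamer_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise PanelError(f"duplicate aptamer ids: {dups[:5]}")
        bad_species = set(self.table["species_target"]) - set(SPECIES_VALUES)
        if bad_species:
            raise PanelError(f"unknown species_target values: {sorted(bad_species)}")
        for sym in self.table["gene_symbol"]:
            if sym and any(part == "" for part in sym.split("|")):
                raise PanelError(f"compound gene symbol with empty component: {sym!r}")

    @property
    def aptamer_ids(self) -> list[str]:
        return list(self.table["aptamer_id"])

    def gene_symbols(self, split_compound: bool = True) -> set[str]:
        """Unique non-empty gene symbols; compound symbols optionally split on '|'."""
        out: set[str] = set()
        for sym in self.table["gene_symbol"]:
            if not sym:
                continue
            if split_compound:
                out.update(sym.split("|"))
            else:
                out.add(sym)
        return out

    def subset(self, aptamer_ids: Iterable[str]) -> "AptamerPanel":
        keep = set(aptamer_ids)
        return AptamerPanel(self.table[self.table["aptamer_id"].isin(keep)])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ProteomeMatrix:
    """Sample x aptamer grid of log2 RFU values."""

    values: pd.DataFrame  # index = sample_ids, columns = aptamer_ids

    def __post_init__(self) -> None:
        vals = self.values
        if vals.index.duplicated().any():
            raise PanelError("duplicate sample ids in matrix")
        if vals.columns.duplicated().any():
            raise PanelError("duplicate aptamer ids in matrix")
        arr = vals.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise PanelError(
                "non-finite value at sample "
                f"{vals.index[bad[0]]!r}, aptamer {vals.columns[bad[1]]!r}"
            )
        self.values = vals.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def aptamer_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_aptamers(self, aptamer_ids: Iterable[str]) -> "ProteomeMatrix":
        keep = [a for a in self.aptamer_ids if a in set(aptamer_ids)]
        return ProteomeMatrix(self.values[keep])

    def subset_samples(self, sample_ids: Iterable[str]) -> "ProteomeMatrix":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return ProteomeMatrix(self.values.loc[keep])


@dataclass
class SampleMetadata:
    """Per-sample covariates: genotype, model, sex, cohort batch label, age."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.table.columns]
        if missing:
            raise PanelError(f"metadata missing columns: {missing}")
        tbl = self.table[METADATA_COLUMNS].reset_index(drop=True).copy()
        for col in ("sample_id", "genotype", "model", "sex", "cohort"):
            tbl[col] = tbl[col].astype(str)
        tbl["age_months"] = tbl["age_months"].astype(float)
        if tbl["sample_id"].duplicated().any():
            raise PanelError("duplicate sample ids in metadata")
        for col, allowed in (
            ("genotype", GENOTYPE_VALUES),
            ("model", MODEL_VALUES),
            ("sex", SEX_VALUES),
        ):
            bad = set(tbl[col]) - set(allowed)
            if bad:
                raise PanelError(f"invalid {col} values: {sorted(bad)}")
        if (tbl["age_months"] <= 0).any():
            raise PanelError("age_months must be positive")
        self.table = tbl

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def aligned_to(self, matrix: ProteomeMatrix) -> "SampleMetadata":
        """Reorder rows to the matrix's sample order; sets must be identical."""
        if set(self.sample_ids) != set(matrix.sample_ids):
            raise PanelError("metadata and matrix sample ids differ as sets")
        tbl = self.table.set_index("sample_id").loc[matrix.sample_ids].reset_index()
        return SampleMetadata(tbl)

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        keep = set(sample_ids)
        return SampleMetadata(self.table[self.table["sample_id"].isin(keep)])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. GO terms) as sets of gene symbols."""

    sets: dict[str, set[str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise PanelError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]


@dataclass
class FilterReport:
    """Bookkeeping of the panel filtering rules."""

    n_input: int = 0
    n_dropped_unmapped: int = 0
    n_dropped_ortholog_duplicate: int = 0
    n_kept: int = 0
    multi_aptamer_symbols_flagged: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_proteome_table(
    path: str | Path,
    scale: str = "raw",
    panel_path: str | Path | None = None,
) -> tuple[ProteomeMatrix, AptamerPanel, SampleMetadata]:
    """Read an ADAT-lite sample table (+ optional panel annotation file).

    Parameters
    ----------
    path
        Delimited file with the METADATA_COLUMNS followed by one column per
        aptamer. Delimiter inferred from the extension (.tsv/.txt = tab).
    scale
        ``"raw"`` (RFU; strictly positive, log2-transformed on read) or
        ``"log2"`` (passed through unchanged).
    panel_path
        Optional panel annotation table. When absent a minimal panel with
        empty annotations is synthesized from the matrix columns.
    """
    if scale not in ("raw", "log2"):
        raise PanelError(f"scale must be 'raw' or 'log2', got {scale!r}")
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"proteome table missing metadata columns: {missing}")
    if df.isna().any().any():
        raise PanelError("proteome table has missing values (ragged rows?)")
    meta = SampleMetadata(df[METADATA_COLUMNS])
    apt_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    vals = df[apt_cols].astype(float)
    vals.index = pd.Index(df["sample_id"].astype(str))
    vals.index.name = None
    if scale == "raw":
        arr = vals.to_numpy()
        if (arr <= 0).any():
            i, j = np.argwhere(arr <= 0)[0]
            raise PanelError(
                f"non-positive raw RFU for sample {vals.index[i]!r}, "
                f"aptamer {vals.columns[j]!r}"
            )
        vals = np.log2(vals)
    matrix = ProteomeMatrix(vals)
    if panel_path is not None:
        panel = read_panel(panel_path)
        if set(panel.aptamer_ids) != set(apt_cols):
            raise PanelError("panel aptamer ids do not match matrix columns")
    else:
        panel = AptamerPanel(
            pd.DataFrame(
                {
                    "aptamer_id": apt_cols,
                    "gene_symbol": "",
                    "uniprot_id": "",
                    "species_target": "unknown",
                }
            )
        )
    return matrix, panel, meta


def write_proteome_table(
    path: str | Path,
    matrix: ProteomeMatrix,
    metadata: SampleMetadata,
    scale: str = "log2",
) -> None:
    """Write matrix+metadata as one ADAT-lite table (log2 or raw = 2**log2)."""
    meta = metadata.aligned_to(matrix)
    vals = matrix.values
    if scale == "raw":
        vals = np.exp2(vals)
    elif scale != "log2":
        raise PanelError(f"scale must be 'raw' or 'log2', got {scale!r}")
    out = pd.concat([meta.table.set_index("sample_id"), vals], axis=1)
    out.index.name = "sample_id"
    out.reset_index().to_csv(path, sep=_sep_for(path), index=False)


def read_panel(path: str | Path) -> AptamerPanel:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    return AptamerPanel(df)


def write_panel(path: str | Path, panel: AptamerPanel) -> None:
    panel.table.to_csv(path, sep=_sep_for(path), index=False)


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str})
    return SampleMetadata(df)


def write_metadata(path: str | Path, metadata: SampleMetadata) -> None:
    metadata.table.to_csv(path, sep=_sep_for(path), index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format: name <tab> description <tab> member...

    Duplicate members within a set are deduplicated; duplicate set names and
    lines with fewer than three fields are errors.
    """
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PanelError(f"GMT line {lineno}: fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise PanelError(f"GMT line {lineno}: duplicate set name {name!r}")
            members = {m for m in fields[2:] if m}
            if not members:
                raise PanelError(f"GMT line {lineno}: set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets)


def write_gmt(path: str | Path, collection: GeneSetCollection) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Panel filtering
# ---------------------------------------------------------------------------

def filter_panel(
    panel: AptamerPanel, matrix: ProteomeMatrix | None = None
) -> tuple[AptamerPanel, ProteomeMatrix | None, FilterReport]:
    """Apply the pre-analysis aptamer filters.

    Rules, in order:
    1. drop aptamers with no assigned gene symbol;
    2. for any gene symbol measured by exactly one human-target and one
       mouse-target aptamer (an ortholog duplicate pair), keep only the
       mouse-specific aptamer.

    Symbols carried by three or more aptamers are all retained and flagged in
    the report. Idempotent: a filtered panel passes through unchanged.
    """
    report = FilterReport(n_input=len(panel))
    tbl = panel.table
    mapped = tbl[tbl["gene_symbol"] != ""]
    report.n_dropped_unmapped = len(tbl) - len(mapped)

    drop_ids: set[str] = set()
    flagged: list[str] = []
    for sym, grp in mapped.groupby("gene_symbol", sort=True):
        if len(grp) == 2:
            species = set(grp["species_target"])
            if species == {"human", "mouse"}:
                human_row = grp[grp["species_target"] == "human"]
                drop_ids.update(human_row["aptamer_id"])
        elif len(grp) >= 3:
            flagged.append(str(sym))
    report.n_dropped_ortholog_duplicate = len(drop_ids)
    report.multi_aptamer_symbols_flagged = flagged

    kept = mapped[~mapped["aptamer_id"].isin(drop_ids)]
    report.n_kept = len(kept)
    out_panel = AptamerPanel(kept)
    out_matrix = None
    if matrix is not None:
        if set(panel.aptamer_ids) != set(matrix.aptamer_ids):
            raise PanelError("panel and matrix aptamer ids differ")
        out_matrix = matrix.subset_aptamers(out_panel.aptamer_ids)
    return out_panel, out_matrix, report
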